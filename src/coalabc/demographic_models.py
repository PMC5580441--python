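"""Three-deme demographic models A-G with uniform priors.

All models share the topology ((chilensis, pallatangae), albiceps): the
sister pair merges at T_CP generations in the past, their ancestor merges
with albiceps at T_A. Deme sizes are constant; ancestral demes inherit the
size of the receiving deme (pallatangae folds into chilensis, chilensis
into albiceps). The models differ only in their migration structure:

=====  ==========================================================
code   migration (backward per-lineage probability per generation)
=====  ==========================================================
A      none
B      chilensis <-> pallatangae, one symmetric rate
C      chilensis <-> albiceps, one symmetric rate
D      both B and C edges sharing a single rate ("equal gene flow")
E      all three pairs, one symmetric rate each
F      B and C edges with independent rates, m_CP > m_CA
G      as F, but both edges shut off for the most recent T_iso
       generations (isolation since the last glacial maximum,
       ~20 kyr at a one-year generation time)
=====  ==========================================================

Internal deme indices are 0 = chilensis, 1 = pallatangae, 2 = albiceps.
Models F and G were designed for the nuclear track only; requesting them
for a mitochondrial analysis is a scope error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CoalABCError, ScopeError

DEMES = ("chilensis", "pallatangae", "albiceps")
C, P, A = 0, 1, 2

MODEL_CODES = ("A", "B", "C", "D", "E", "F", "G")
#: Models of the shared nuclear/mitochondrial comparison (set 1) and the
#: nuclear-only refinement stage (set 2).
MODEL_SET_1 = ("A", "B", "C", "D", "E")
MODEL_SET_2 = ("D", "F", "G")

#: Default end of gene flow for model G, in generations before present
#: (20 kyr at a 1-year generation time).
DEFAULT_T_ISO = 20_000.0


@dataclass(frozen=True)
class MigrationEdge:
    """Symmetric migration between two demes, active for t >= t_start.

    ``rate_param`` names the entry of the parameter vector holding the
    backward per-lineage per-generation migration probability. ``t_start``
    is 0 for continuous gene flow and T_iso for the glacial-window model.
    """

    deme_i: int
    deme_j: int
    rate_param: str
    t_start: float = 0.0


@dataclass(frozen=True)
class PriorSet:
    """Independent uniform prior bounds for every demographic parameter."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior {name!r}: lower {lo} !< upper {hi}")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bounds[name]

    @classmethod
    def nuclear_default(cls) -> "PriorSet":
        return cls(
            {
                "N_chilensis": (10.0, 100_000.0),
                "N_pallatangae": (10.0, 100_000.0),
                "N_albiceps": (10.0, 100_000.0),
                "T_cp": (10_000.0, 2_000_000.0),
                "T_a": (1_000_000.0, 7_000_000.0),
                "m_cp": (1e-8, 1e-4),
                "m_ca": (1e-8, 1e-4),
                "m_pa": (1e-8, 1e-4),
                "m_all": (1e-8, 1e-4),
            }
        )

    @classmethod
    def mitochondrial_default(cls) -> "PriorSet":
        """As nuclear, with the effective-size bound quartered (maternal,
        haploid inheritance); time and migration priors unchanged."""
        base = cls.nuclear_default().bounds.copy()
        for n in ("N_chilensis", "N_pallatangae", "N_albiceps"):
            lo, hi = base[n]
            base[n] = (lo, hi / 4.0)
        return cls(base)


@dataclass(frozen=True)
class DemographicModel:
    """One of the seven gene-flow models, with its free-parameter list."""

    code: str
    marker_set: str
    edges: tuple[MigrationEdge, ...]
    free_parameters: tuple[str, ...]
    #: pairs (low, high) whose draws must satisfy low < high
    ordering_constraints: tuple[tuple[str, str], ...] = ()
    t_iso: float = 0.0

    @property
    def n_parameters(self) -> int:
        return len(self.free_parameters)


_BASE_PARAMS = ("N_chilensis", "N_pallatangae", "N_albiceps", "T_cp", "T_a")


def get_model(
    code: str, marker_set: str = "nuclear", t_iso: float = DEFAULT_T_ISO
) -> DemographicModel:
    """Build the fully specified model for one code and marker set."""
    if code not in MODEL_CODES:
        raise CoalABCError(f"unknown model code {code!r}")
    if marker_set not in ("nuclear", "mitochondrial"):
        raise ValueError(f"unknown marker_set {marker_set!r}")
    if marker_set == "mitochondrial" and code in ("F", "G"):
        raise ScopeError(
            f"model {code} was defined for the nuclear track only"
        )
    edges: tuple[MigrationEdge, ...] = ()
    extra: tuple[str, ...] = ()
    ordering: tuple[tuple[str, str], ...] = ()
    model_t_iso = 0.0
    if code == "B":
        edges = (MigrationEdge(C, P, "m_cp"),)
        extra = ("m_cp",)
    elif code == "C":
        edges = (MigrationEdge(C, A, "m_ca"),)
        extra = ("m_ca",)
    elif code == "D":
        edges = (MigrationEdge(C, P, "m_all"), MigrationEdge(C, A, "m_all"))
        extra = ("m_all",)
    elif code == "E":
        edges = (
            MigrationEdge(C, P, "m_cp"),
            MigrationEdge(C, A, "m_ca"),
            MigrationEdge(P, A, "m_pa"),
        )
        extra = ("m_cp", "m_ca", "m_pa")
    elif code == "F":
        edges = (MigrationEdge(C, P, "m_cp"), MigrationEdge(C, A, "m_ca"))
        extra = ("m_cp", "m_ca")
        ordering = (("m_ca", "m_cp"),)
    elif code == "G":
        edges = (
            MigrationEdge(C, P, "m_cp", t_start=t_iso),
            MigrationEdge(C, A, "m_ca", t_start=t_iso),
        )
        extra = ("m_cp", "m_ca")
        ordering = (("m_ca", "m_cp"),)
        model_t_iso = t_iso
    return DemographicModel(
        code=code,
        marker_set=marker_set,
        edges=edges,
        free_parameters=_BASE_PARAMS + extra,
        ordering_constraints=(("T_cp", "T_a"),) + ordering,
        t_iso=model_t_iso,
    )


def default_priors(marker_set: str) -> PriorSet:
    if marker_set == "nuclear":
        return PriorSet.nuclear_default()
    if marker_set == "mitochondrial":
        return PriorSet.mitochondrial_default()
    raise ValueError(f"unknown marker_set {marker_set!r}")


_MAX_REDRAWS = 1_000_000


def draw_parameters(
    model: DemographicModel, priors: PriorSet, rng: np.random.Generator
) -> dict[str, float]:
    """One joint draw from the independent uniform priors.

    Ordering constraints (T_cp < T_a; m_ca < m_cp for models F/G) are
    enforced by redrawing the violating subset, which leaves each marginal
    uniform on the accepted region.
    """
    params = {
        name: float(rng.uniform(*priors[name])) for name in model.free_parameters
    }
    for low, high in model.ordering_constraints:
        for _ in range(_MAX_REDRAWS):
            if params[low] < params[high]:
                break
            params[low] = float(rng.uniform(*priors[low]))
            params[high] = float(rng.uniform(*priors[high]))
        else:  # pragma: no cover - astronomically unlikely
            raise CoalABCError(f"constraint {low} < {high} never satisfied")
    return params


def active_migration_rates(
    model: DemographicModel, params: dict[str, float], t: float
) -> np.ndarray:
    """Backward per-lineage migration rate matrix among extant demes at t.

    Entry [i, j] is the rate at which a lineage currently in deme i traces
    back into deme j. Edges are inactive before their window opens
    (model G's glacial window) and once an endpoint deme has merged; after
    T_cp the chilensis-pallatangae ancestor exchanges no migrants with
    albiceps, so the matrix is zero for t >= T_cp.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    rates = np.zeros((3, 3))
    if t >= params["T_cp"]:
        return rates
    for edge in model.edges:
        if t < edge.t_start:
            continue
        m = params[edge.rate_param]
        rates[edge.deme_i, edge.deme_j] += m
        rates[edge.deme_j, edge.deme_i] += m
    return rates


@dataclass(frozen=True)
class EpochTable:
    """Piecewise-constant demography handed to the simulation core.

    ``bounds[k]`` ends epoch k (ascending, last = +inf); ``migration[k]``
    is the 3x3 backward rate matrix inside epoch k; at the close of epoch k
    all lineages of ``merge_from[k]`` move into ``merge_to[k]`` (-1 = no
    merge).
    """

    bounds: np.ndarray
    migration: np.ndarray
    merge_from: np.ndarray
    merge_to: np.ndarray


def build_epochs(model: DemographicModel, params: dict[str, float]) -> EpochTable:
    """Resolve a model + draw into the epoch table the simulator consumes."""
    t_cp, t_a = params["T_cp"], params["T_a"]
    if not t_cp < t_a:
        raise CoalABCError("draw violates T_cp < T_a")
    events: list[tuple[float, int, int]] = [(t_cp, P, C), (t_a, C, A)]
    starts = sorted({e.t_start for e in model.edges if 0.0 < e.t_start < t_cp})
    bounds, mig, mfrom, mto = [], [], [], []
    prev = 0.0
    for t in starts + [t_cp, t_a, np.inf]:
        # the matrix is constant inside [prev, t); evaluate at its left edge
        mig.append(active_migration_rates(model, params, prev))
        bounds.append(t)
        merge = next(((f, to) for tt, f, to in events if tt == t), (-1, -1))
        mfrom.append(merge[0])
        mto.append(merge[1])
        prev = t
    return EpochTable(
        bounds=np.asarray(bounds, dtype=np.float64),
        migration=np.asarray(mig, dtype=np.float64),
        merge_from=np.asarray(mfrom, dtype=np.int64),
        merge_to=np.asarray(mto, dtype=np.int64),
    )
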