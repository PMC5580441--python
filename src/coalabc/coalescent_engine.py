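"""Structured-coalescent simulation of multilocus sequence data.

One simulation draws an independent gene genealogy per locus (free
recombination between loci, none within), drops infinite-sites mutations on
it and summarises the result with exactly the statistic definitions used
for observed data. Loci are scaled by inheritance: an autosomal locus in a
deme of N diploids coalesces among 2N gene copies, the mitochondrial locus
among N (the quartered effective size is carried by the mitochondrial
prior, not by an extra scaling here).

Mutation model: infinite sites per locus — every mutation creates a new
biallelic site, encoded A (ancestral) / T (derived) on export. All default
summary statistics depend only on segregating-site patterns, for which this
is equivalent to a finite-site model at these divergences but cheaper and
free of multiple-hit bias. If a draw ever produces more mutations than
sites, the locus falls back to finite sites (uniform site per mutation,
toggling on multiple hits) with a warning.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._simcore import simulate_tree
from .demographic_models import (
    DEMES,
    DemographicModel,
    EpochTable,
    build_epochs,
)
from .errors import CoalABCError
from .popgen_stats import StatVector, aggregate_stat_vector
from .sequence_data import FOCAL_TAXA, LocusAlignment, MultiLocusDataset

#: Default per-site per-generation mutation rates (order-of-magnitude avian
#: conventions; the source study does not publish the rates it used).
DEFAULT_MU_NUCLEAR = 1.0e-9
DEFAULT_MU_MITOCHONDRIAL = 1.0e-8

_PLOIDY_FACTOR = {"autosomal": 2.0, "mitochondrial": 1.0}


@dataclass(frozen=True)
class LocusConfig:
    """Structure of one simulated locus: length, rate, inheritance, samples.

    ``sample_sizes`` maps taxon -> sampled gene copies at this locus (one
    FASTA row = one gene copy), mirroring the observed per-locus presence
    matrix with its missing sample-locus combinations.
    """

    name: str
    length: int
    mu: float
    inheritance: str
    sample_sizes: dict[str, int]

    def __post_init__(self) -> None:
        if self.length <= 0 or self.mu < 0:
            raise ValueError("length must be positive and mu non-negative")
        if self.inheritance not in _PLOIDY_FACTOR:
            raise CoalABCError(
                f"locus {self.name!r}: inheritance {self.inheritance!r} is not "
                "simulated (the Z-linked locus is excluded from these analyses)"
            )
        if sum(self.sample_sizes.values()) < 2:
            raise ValueError(f"locus {self.name!r}: need >=2 sampled copies")


@dataclass(frozen=True)
class SimulationRequest:
    """The locus panel one simulation replicates."""

    loci: tuple[LocusConfig, ...]

    @classmethod
    def from_dataset(
        cls,
        dataset: MultiLocusDataset,
        marker_set: str = "nuclear",
        mu_nuclear: float = DEFAULT_MU_NUCLEAR,
        mu_mitochondrial: float = DEFAULT_MU_MITOCHONDRIAL,
        pops: tuple[str, ...] = FOCAL_TAXA,
    ) -> "SimulationRequest":
        """Mirror an observed dataset's locus panel and presence matrix."""
        if marker_set == "nuclear":
            alns = dataset.loci_by_inheritance("autosomal")
            mu = mu_nuclear
        elif marker_set == "mitochondrial":
            alns = dataset.loci_by_inheritance("mitochondrial")
            mu = mu_mitochondrial
        else:
            raise ValueError(f"unknown marker_set {marker_set!r}")
        loci = []
        for aln in alns:
            sizes = {p: len(dataset.taxon_rows(aln, p)) for p in pops}
            loci.append(
                LocusConfig(aln.locus_name, aln.length, mu, aln.inheritance, sizes)
            )
        return cls(tuple(loci))


@dataclass
class GeneGenealogy:
    """A simulated gene tree over sampled copies.

    Leaves 0..n-1 are ordered deme-major (chilensis, pallatangae, albiceps
    blocks); internal nodes follow in coalescence-time order, so
    ``parent[v] > v`` for every non-root node. ``pop_counts[v, d]`` counts
    sampled copies from deme d below node v.
    """

    parent: np.ndarray
    node_time: np.ndarray
    pop_counts: np.ndarray
    k_init: np.ndarray

    @property
    def n_samples(self) -> int:
        return int(self.k_init.sum())

    @property
    def tmrca(self) -> float:
        return float(self.node_time[-1])

    @property
    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node."""
        v = np.arange(self.parent.size - 1)
        return self.node_time[self.parent[v]] - self.node_time[v]

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())

    def leaf_membership(self) -> np.ndarray:
        """(n_nodes, n) boolean matrix: leaf j descends from node v."""
        n = self.n_samples
        n_nodes = self.parent.size
        member = np.zeros((n_nodes, n), dtype=bool)
        member[np.arange(n), np.arange(n)] = True
        for v in range(n_nodes - 1):
            member[self.parent[v]] |= member[v]
        return member


def _deme_counts(sample_sizes: dict[str, int]) -> np.ndarray:
    k = np.zeros(3, dtype=np.int64)
    for taxon, nn in sample_sizes.items():
        if nn < 0:
            raise ValueError("sample sizes must be >= 0")
        if nn:
            k[DEMES.index(taxon)] = nn
    return k


def simulate_genealogy(
    model: DemographicModel,
    params: dict[str, float],
    request: SimulationRequest,
    locus_index: int,
    rng: np.random.Generator,
) -> GeneGenealogy:
    """Simulate one locus's genealogy under a demographic-model draw."""
    locus = request.loci[locus_index]
    epochs = build_epochs(model, params)
    factor = _PLOIDY_FACTOR[locus.inheritance]
    sizes = np.array(
        [factor * params[f"N_{d}"] for d in DEMES], dtype=np.float64
    )
    k_init = _deme_counts(locus.sample_sizes)
    seed = int(rng.integers(1, 2**31 - 1))
    parent, node_time, pop_counts = simulate_tree(
        seed,
        k_init,
        sizes,
        epochs.bounds,
        epochs.migration,
        epochs.merge_from,
        epochs.merge_to,
    )
    return GeneGenealogy(parent, node_time, pop_counts, k_init)


_PANMICTIC_EPOCHS = EpochTable(
    bounds=np.array([np.inf]),
    migration=np.zeros((1, 3, 3)),
    merge_from=np.array([-1], dtype=np.int64),
    merge_to=np.array([-1], dtype=np.int64),
)


def simulate_panmictic(
    n: int, gene_copies: float, rng: np.random.Generator
) -> GeneGenealogy:
    """Single-deme constant-size coalescent; the analytic-oracle workhorse."""
    k_init = np.array([n, 0, 0], dtype=np.int64)
    sizes = np.array([gene_copies, 1.0, 1.0])
    seed = int(rng.integers(1, 2**31 - 1))
    parent, node_time, pop_counts = simulate_tree(
        seed,
        k_init,
        sizes,
        _PANMICTIC_EPOCHS.bounds,
        _PANMICTIC_EPOCHS.migration,
        _PANMICTIC_EPOCHS.merge_from,
        _PANMICTIC_EPOCHS.merge_to,
    )
    return GeneGenealogy(parent, node_time, pop_counts, k_init)


@dataclass
class SimulatedLocus:
    """Mutations dropped on one genealogy.

    ``branches[i]`` is the node whose parent branch carries mutation i;
    ``sites[i]`` its alignment column. Under infinite sites every mutation
    owns a distinct column; ``finite_sites`` marks the fallback where
    columns may collide (multiple hits toggle the state).
    """

    genealogy: GeneGenealogy
    length: int
    branches: np.ndarray
    sites: np.ndarray
    finite_sites: bool = False

    @property
    def n_mutations(self) -> int:
        return self.branches.size

    def site_derived_counts(self) -> np.ndarray:
        """(n_variable_columns, 3) derived-copy counts per deme per column."""
        if not self.finite_sites:
            return self.genealogy.pop_counts[self.branches]
        # multiple hits: a column's state per leaf is the XOR (hit-count
        # parity) over its mutations' subtree memberships
        member = self.genealogy.leaf_membership()
        uniq, inv = np.unique(self.sites, return_inverse=True)
        hits = np.zeros((uniq.size, self.genealogy.n_samples), dtype=np.int64)
        np.add.at(hits, inv, member[self.branches].astype(np.int64))
        derived = hits % 2 == 1
        demes = np.repeat(np.arange(3), self.genealogy.k_init)
        return np.stack(
            [derived[:, demes == d].sum(axis=1) for d in range(3)], axis=1
        ).astype(np.int64)

    def to_alignment(
        self,
        locus_name: str,
        inheritance: str,
        sample_ids: list[str] | None = None,
    ) -> LocusAlignment:
        """Biallelic A (ancestral) / T (derived) alignment of full length."""
        gen = self.genealogy
        n = gen.n_samples
        if sample_ids is None:
            sample_ids = [f"s{i}" for i in range(n)]
        if len(sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        member = gen.leaf_membership()
        geno = np.zeros((n, self.length), dtype=bool)
        for b, s in zip(self.branches, self.sites):
            geno[member[b], s] ^= True
        alphabet = np.frombuffer(b"AT", dtype=np.uint8)
        arr = alphabet[geno.astype(np.uint8)]
        rows = {
            sid: arr[i].tobytes().decode("ascii")
            for i, sid in enumerate(sample_ids)
        }
        return LocusAlignment(locus_name, inheritance, rows)


def drop_mutations(
    genealogy: GeneGenealogy,
    length: int,
    mu: float,
    rng: np.random.Generator,
) -> SimulatedLocus:
    """Poisson mutations on the genealogy, one distinct site per mutation.

    The mutation count is Poisson(total branch length x mu x length); each
    mutation lands on a branch with probability proportional to its length
    and on a fresh uniformly drawn column. If the count exceeds the column
    budget the locus switches to finite sites (with replacement) and warns.
    """
    blen = genealogy.branch_lengths
    total = float(blen.sum())
    n_mut = int(rng.poisson(total * mu * length))
    if n_mut == 0:
        empty = np.empty(0, dtype=np.int64)
        return SimulatedLocus(genealogy, length, empty, empty)
    u = rng.random(n_mut) * total
    branches = np.searchsorted(np.cumsum(blen), u).astype(np.int64)
    branches = np.minimum(branches, blen.size - 1)
    if n_mut <= length:
        sites = rng.choice(length, size=n_mut, replace=False).astype(np.int64)
        finite = False
    else:
        warnings.warn(
            f"{n_mut} mutations exceed the {length}-site budget; "
            "falling back to finite sites",
            stacklevel=2,
        )
        sites = rng.integers(0, length, size=n_mut).astype(np.int64)
        finite = True
    return SimulatedLocus(genealogy, length, branches, sites, finite)


def _raw_stats_from_counts(
    derived: np.ndarray, k_init: np.ndarray, pops: tuple[str, ...]
) -> np.ndarray:
    """Per-locus [S_p..., pi_p..., S_tot, d_pq...] from derived-count patterns.

    Integer accumulation with a single final division so the result is
    bit-identical to the alignment-based statistics in
    :mod:`coalabc.popgen_stats`.
    """
    demes = [DEMES.index(p) for p in pops]
    npop = np.array([int(k_init[d]) for d in demes])
    if np.any(npop < 2):
        raise ValueError("every population needs >=2 sampled copies")
    kk = len(pops)
    pairs = list(itertools.combinations(range(kk), 2))
    out = np.empty(2 * kk + 1 + len(pairs))
    c = derived[:, demes] if derived.size else np.zeros((0, kk), dtype=np.int64)
    for i in range(kk):
        ci = c[:, i]
        out[i] = int(((ci > 0) & (ci < npop[i])).sum())
        out[kk + i] = int((ci * (npop[i] - ci)).sum()) / (
            npop[i] * (npop[i] - 1) / 2
        )
    ctot = c.sum(axis=1)
    ntot = int(npop.sum())
    out[2 * kk] = int(((ctot > 0) & (ctot < ntot)).sum())
    for j, (p, q) in enumerate(pairs):
        cross = int(
            (c[:, p] * (npop[q] - c[:, q]) + c[:, q] * (npop[p] - c[:, p])).sum()
        )
        out[2 * kk + 1 + j] = cross / (npop[p] * npop[q])
    return out


def simulate_stat_vector(
    model: DemographicModel,
    params: dict[str, float],
    request: SimulationRequest,
    rng: np.random.Generator,
    pops: tuple[str, ...] = FOCAL_TAXA,
) -> StatVector:
    """Simulate every locus independently and aggregate the shared stat set."""
    per_locus = np.empty(
        (len(request.loci), 2 * len(pops) + 1 + len(pops) * (len(pops) - 1) // 2)
    )
    for i in range(len(request.loci)):
        locus = request.loci[i]
        gen = simulate_genealogy(model, params, request, i, rng)
        sim = drop_mutations(gen, locus.length, locus.mu, rng)
        per_locus[i] = _raw_stats_from_counts(
            sim.site_derived_counts(), gen.k_init, pops
        )
    return aggregate_stat_vector(per_locus, pops)
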