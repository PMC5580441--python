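"""Population-genetic summary statistics and genetic distances.

All statistics share one site-handling rule: a site enters a comparison only
where every sequence involved carries an unambiguous base (A/C/G/T). IUPAC
ambiguity codes — unphased heterozygous calls — and missing symbols are
excluded sitewise, the pairwise-deletion convention used for raw p-distances.

The statistic vector fed to ABC is, for populations ``p`` and pairs
``(p, q)`` in a fixed documented order::

    [S_p ...] [pi_p ...] S_tot [d_pq ...] [FST_pq ...]

with S the number of segregating sites, pi the mean number of pairwise
differences (per locus, not per site), d_pq the mean between-population
pairwise differences and FST the Hudson-type ratio estimator
``1 - pi_within / pi_between``. Multilocus aggregation is the arithmetic
mean across loci for S, pi and d; the FST entries are computed from the
across-locus means (ratio of averages), which is robust to individual
monomorphic loci.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, UndefinedStatisticError
from .sequence_data import FOCAL_TAXA, LocusAlignment, MultiLocusDataset

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _as_array(seqs) -> np.ndarray:
    """Sequences (strings or a LocusAlignment byte matrix) -> uint8 matrix."""
    if isinstance(seqs, np.ndarray):
        return seqs
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must share one length")
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), len(seqs[0])
    )


def _good(arr: np.ndarray) -> np.ndarray:
    """Mask of sites carrying an unambiguous base."""
    return (
        (arr == _BASES[0]) | (arr == _BASES[1]) | (arr == _BASES[2]) | (arr == _BASES[3])
    )


def pairwise_p_distance(seq_a: str, seq_b: str) -> float:
    """Raw p-distance with pairwise deletion of missing/ambiguous sites.

    Raises :class:`UndefinedStatisticError` when no site is comparable —
    deliberately distinct from a distance of 0.0.
    """
    arr = _as_array([seq_a, seq_b])
    good = _good(arr).all(axis=0)
    n_comp = int(good.sum())
    if n_comp == 0:
        raise UndefinedStatisticError("no comparable unambiguous sites")
    diffs = int((arr[0, good] != arr[1, good]).sum())
    return diffs / n_comp


def _mean_pairwise_distance(pairs) -> float:
    """Mean p-distance over an iterable of (seq, seq) pairs; NaN-free."""
    vals = [pairwise_p_distance(a, b) for a, b in pairs]
    return float(np.mean(vals))


def net_between_group_distance(group_x, group_y) -> float:
    """Net between-group mean raw p-distance.

    ``d_net = mean_{a in X, b in Y} d(a, b) - (dxx + dyy) / 2`` where dxx,
    dyy are mean within-group distances (0 for singleton groups).
    """
    group_x, group_y = list(group_x), list(group_y)
    if not group_x or not group_y:
        raise ValueError("both groups must be non-empty")
    d_between = _mean_pairwise_distance(itertools.product(group_x, group_y))
    d_xx = (
        _mean_pairwise_distance(itertools.combinations(group_x, 2))
        if len(group_x) > 1
        else 0.0
    )
    d_yy = (
        _mean_pairwise_distance(itertools.combinations(group_y, 2))
        if len(group_y) > 1
        else 0.0
    )
    return d_between - (d_xx + d_yy) / 2.0


def _base_counts(arr: np.ndarray) -> np.ndarray:
    """(4, length) counts of A/C/G/T per column."""
    return np.stack([(arr == b).sum(axis=0) for b in _BASES], axis=0)


def segregating_sites(pop) -> int:
    """Number of columns with >=2 distinct unambiguous bases in the sample."""
    arr = _as_array(pop)
    if arr.shape[0] < 2:
        raise InsufficientDataError("segregating sites need >=2 sequences")
    counts = _base_counts(arr)
    return int(((counts > 0).sum(axis=0) >= 2).sum())


def mean_pairwise_differences(pop) -> float:
    """Mean count of differing unambiguous sites over all unordered pairs.

    Per-pair pairwise deletion: a site counts for a pair only when both
    members carry an unambiguous base there. Reported per locus (a count),
    not per site.
    """
    arr = _as_array(pop)
    n = arr.shape[0]
    if n < 2:
        raise InsufficientDataError("pairwise differences need >=2 sequences")
    good = _good(arr)
    total = 0
    for i in range(n - 1):
        both = good[i] & good[i + 1 :]
        diff = (arr[i] != arr[i + 1 :]) & both
        total += int(diff.sum())
    return total / (n * (n - 1) / 2)


def mean_between_differences(pop_x, pop_y) -> float:
    """Mean count of differing unambiguous sites over all between-pop pairs."""
    ax, ay = _as_array(pop_x), _as_array(pop_y)
    if ax.shape[0] == 0 or ay.shape[0] == 0:
        raise InsufficientDataError("between-population differences need both pops")
    gx, gy = _good(ax), _good(ay)
    total = 0
    for i in range(ax.shape[0]):
        both = gx[i] & gy
        total += int(((ax[i] != ay) & both).sum())
    return total / (ax.shape[0] * ay.shape[0])


def pairwise_fst(pop_x, pop_y) -> float:
    """Hudson-type FST: ``1 - pi_within / pi_between``.

    ``pi_within`` is the unweighted mean of the two within-population mean
    pairwise differences; ``pi_between`` the mean between-population pairwise
    differences. Clamped to [-1, 1]; undefined (signalled) when
    ``pi_between`` is zero.
    """
    pop_x, pop_y = list(pop_x), list(pop_y)
    if len(pop_x) < 2 or len(pop_y) < 2:
        raise InsufficientDataError("FST needs >=2 sequences per population")
    pi_b = mean_between_differences(pop_x, pop_y)
    if pi_b == 0.0:
        raise UndefinedStatisticError("zero between-population diversity")
    pi_w = (mean_pairwise_differences(pop_x) + mean_pairwise_differences(pop_y)) / 2.0
    return float(np.clip(1.0 - pi_w / pi_b, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Statistic vectors


def stat_vector_names(pops: tuple[str, ...] = FOCAL_TAXA) -> list[str]:
    """Fixed ordering shared by observed and simulated vectors."""
    pairs = list(itertools.combinations(pops, 2))
    return (
        [f"S_{p}" for p in pops]
        + [f"pi_{p}" for p in pops]
        + ["S_total"]
        + [f"d_{p}_{q}" for p, q in pairs]
        + [f"fst_{p}_{q}" for p, q in pairs]
    )


@dataclass
class StatVector:
    """Named summary-statistic vector with a documented fixed ordering."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("statistic vector contains non-finite values")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)

    def to_csv(self, path) -> None:
        self.as_series().to_frame().T.to_csv(path, index=False)


def _per_locus_raw_stats(pop_seqs: list[list[str]]) -> np.ndarray:
    """[S_p..., pi_p..., S_tot, d_pq...] for one locus (no FST)."""
    k = len(pop_seqs)
    pairs = list(itertools.combinations(range(k), 2))
    out = np.empty(2 * k + 1 + len(pairs))
    for i, seqs in enumerate(pop_seqs):
        out[i] = segregating_sites(seqs)
        out[k + i] = mean_pairwise_differences(seqs)
    pooled = [s for seqs in pop_seqs for s in seqs]
    out[2 * k] = segregating_sites(pooled)
    for j, (p, q) in enumerate(pairs):
        out[2 * k + 1 + j] = mean_between_differences(pop_seqs[p], pop_seqs[q])
    return out


def aggregate_stat_vector(
    per_locus: np.ndarray, pops: tuple[str, ...]
) -> StatVector:
    """Mean the per-locus raw stats and derive FST from the means.

    ``per_locus`` is (n_loci, 2k+1+n_pairs) in the raw-stat ordering. FST for
    each pair is the ratio-of-averages Hudson estimator
    ``1 - mean(pi_w) / mean(d_pq)``, set to 0 when the between-mean is zero
    (monomorphic data carry no differentiation signal).
    """
    k = len(pops)
    pairs = list(itertools.combinations(range(k), 2))
    means = per_locus.mean(axis=0)
    fst = np.empty(len(pairs))
    for j, (p, q) in enumerate(pairs):
        pi_w = (means[k + p] + means[k + q]) / 2.0
        d_b = means[2 * k + 1 + j]
        fst[j] = 0.0 if d_b == 0.0 else np.clip(1.0 - pi_w / d_b, -1.0, 1.0)
    return StatVector(stat_vector_names(pops), np.concatenate([means, fst]))


def observed_stat_vector(
    dataset: MultiLocusDataset,
    pops: tuple[str, ...] = FOCAL_TAXA,
    marker_set: str = "nuclear",
) -> StatVector:
    """Summary-statistic vector from an observed multilocus dataset.

    ``marker_set`` selects autosomal loci ("nuclear") or the mitochondrial
    locus ("mitochondrial"); the Z-linked locus never enters (it was dropped
    from the demographic analyses). Every listed population must have >=2
    sequences in every included locus.
    """
    if marker_set == "nuclear":
        loci = dataset.loci_by_inheritance("autosomal")
    elif marker_set == "mitochondrial":
        loci = dataset.loci_by_inheritance("mitochondrial")
    else:
        raise ValueError(f"unknown marker_set {marker_set!r}")
    if not loci:
        raise InsufficientDataError(f"no {marker_set} loci in dataset")
    rows = []
    for aln in loci:
        pop_seqs = [dataset.taxon_rows(aln, p) for p in pops]
        for p, seqs in zip(pops, pop_seqs):
            if len(seqs) < 2:
                raise InsufficientDataError(
                    f"population {p!r} has <2 sequences at locus {aln.locus_name!r}"
                )
        rows.append(_per_locus_raw_stats(pop_seqs))
    return aggregate_stat_vector(np.asarray(rows), pops)


# ---------------------------------------------------------------------------
# Distance matrices


@dataclass
class DistanceMatrix:
    """Symmetric net between-taxon distance matrix for one marker class."""

    taxa: list[str]
    values: np.ndarray
    marker: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    def to_csv(self, path) -> None:
        self.as_frame().to_csv(path)


def distance_matrix(
    dataset: MultiLocusDataset,
    taxa: tuple[str, ...] = FOCAL_TAXA,
    marker: str = "nuclear",
) -> DistanceMatrix:
    """Net between-taxon mean raw p-distances.

    Mitochondrial: computed on the single mitochondrial locus. Nuclear:
    computed per autosomal locus and averaged across loci (a taxon pair
    enters a locus's average only when both taxa have sequences there).
    """
    if marker == "nuclear":
        loci = dataset.loci_by_inheritance("autosomal")
    elif marker == "mitochondrial":
        loci = dataset.loci_by_inheritance("mitochondrial")
    else:
        raise ValueError(f"unknown marker {marker!r}")
    n = len(taxa)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        vals = []
        for aln in loci:
            gx = dataset.taxon_rows(aln, taxa[i])
            gy = dataset.taxon_rows(aln, taxa[j])
            if gx and gy:
                vals.append(net_between_group_distance(gx, gy))
        if not vals:
            raise InsufficientDataError(
                f"no locus covers both {taxa[i]!r} and {taxa[j]!r}"
            )
        out[i, j] = out[j, i] = float(np.mean(vals))
    return DistanceMatrix(list(taxa), out, marker)
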