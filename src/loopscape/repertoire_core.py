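"""Loop clustering, square-root weighting and sitewise frequency matrices.

The clustering contract: unique sequences are visited in descending read-count
order (lexicographic tie-break); a sequence joins the first existing centroid
whose global-alignment identity is at or above the threshold, otherwise it
founds a new cluster.  Identity is matches / alignment length under a global
alignment scoring match 1, mismatch 0, gap 0 (ties broken toward the fewest
gap columns, i.e. the shortest alignment among match-maximal ones).

For speed, centroid search uses an exact upper bound on match count derived
from amino-acid composition (half of ``len(a) + len(b) - L1(counts)``); only
pairs whose bound clears the threshold are verified by dynamic programming.
The bound is exact, so results equal brute-force greedy clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .alphabet import AA20, site_sort_key
from .library_model import LibraryDesign
from .population_sim import Population, SimulatedClone
from .seq_processing import align_loop

_AA_INDEX = {a: i for i, a in enumerate(AA20)}


# ---------------------------------------------------------------------------
# Background removal
# ---------------------------------------------------------------------------

def remove_background(
    pop: Population, fraction: float = 0.02, mode: str = "read_share"
) -> Population:
    """Drop the rarest sequences amounting to at most ``fraction`` of reads.

    ``read_share`` (default): unique sequences sorted by ascending count are
    removed while their cumulative read share stays at or below ``fraction``;
    a count-tied group is removed only as a whole.  ``unique_share`` instead
    drops the bottom ``fraction`` of unique sequences (same tie rule).
    """
    if not (0.0 <= fraction < 0.5):
        raise ValueError("fraction must be in [0, 0.5)")
    if not pop.clones:
        raise ValueError("empty population")
    if fraction == 0.0:
        return pop
    order = sorted(pop.clones, key=lambda c: (c.read_count, c.dna))
    total = pop.total_count if mode == "read_share" else len(pop.clones)
    budget = fraction * total + 1e-12
    removed: set[int] = set()
    cum = 0.0
    i = 0
    while i < len(order):
        j = i
        group_amount = 0.0
        while j < len(order) and order[j].read_count == order[i].read_count:
            group_amount += order[j].read_count if mode == "read_share" else 1
            j += 1
        if cum + group_amount <= budget:
            removed.update(id(order[k]) for k in range(i, j))
            cum += group_amount
            i = j
        else:
            break
    survivors = [c for c in pop.clones if id(c) not in removed]
    return Population(clones=survivors, label=pop.label)


# ---------------------------------------------------------------------------
# Pairwise identity (global alignment, match 1 / mismatch 0 / gap 0)
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Identity = matches / alignment length of the max-match global alignment.

    Among alignments maximizing matches, the one with the most aligned pairs
    (fewest gap columns) defines the alignment length ``len(a)+len(b)-pairs``.
    """
    if not a and not b:
        return 1.0
    la, lb = len(a), len(b)
    # DP over (matches, pairs), maximized lexicographically.
    prev = [(0, 0)] * (lb + 1)
    for i in range(1, la + 1):
        cur = [(0, 0)] * (lb + 1)
        for j in range(1, lb + 1):
            m, p = prev[j - 1]
            diag = (m + (a[i - 1] == b[j - 1]), p + 1)
            cur[j] = max(diag, prev[j], cur[j - 1])
        prev = cur
    matches, pairs = prev[lb]
    return matches / (la + lb - pairs)


def _count_vector(seq: str) -> np.ndarray:
    v = np.zeros(len(AA20), dtype=np.float64)
    for ch in seq:
        v[_AA_INDEX[ch]] += 1.0
    return v


def _batch_identity(pairs: list[tuple[str, str]]) -> np.ndarray:
    """Vectorized :func:`pairwise_identity` over many sequence pairs.

    Pairs are grouped by length combination; the lexicographic (matches,
    pairs) objective is packed into one integer (``matches * 64 + pairs``,
    valid for sequences shorter than 64 residues).
    """
    out = np.empty(len(pairs))
    by_shape: dict[tuple[int, int], list[int]] = {}
    for idx, (a, b) in enumerate(pairs):
        by_shape.setdefault((len(a), len(b)), []).append(idx)
    for (la, lb), idxs in by_shape.items():
        g = len(idxs)
        if la == 0 and lb == 0:
            out[idxs] = 1.0
            continue
        a_enc = np.frombuffer(
            "".join(pairs[i][0] for i in idxs).encode(), dtype=np.uint8
        ).reshape(g, la) if la else np.empty((g, 0), dtype=np.uint8)
        b_enc = np.frombuffer(
            "".join(pairs[i][1] for i in idxs).encode(), dtype=np.uint8
        ).reshape(g, lb) if lb else np.empty((g, 0), dtype=np.uint8)
        prev = np.zeros((g, lb + 1), dtype=np.int64)
        for i in range(1, la + 1):
            cur = np.zeros((g, lb + 1), dtype=np.int64)
            ai = a_enc[:, i - 1]
            for j in range(1, lb + 1):
                diag = prev[:, j - 1] + 64 * (ai == b_enc[:, j - 1]) + 1
                np.maximum(diag, prev[:, j], out=diag)
                np.maximum(diag, cur[:, j - 1], out=diag)
                cur[:, j] = diag
            prev = cur
        matches = prev[:, lb] >> 6
        aligned_pairs = prev[:, lb] & 63
        out[idxs] = matches / (la + lb - aligned_pairs)
    return out


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    centroid: str
    members: list[tuple[str, int]] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(c for _, c in self.members)


@dataclass
class LoopClusterSet:
    loop_id: str
    identity_threshold: float
    clusters: list[Cluster]

    def __len__(self) -> int:
        return len(self.clusters)


def cluster_loops(
    items: list[tuple[str, int]],
    loop_id: str = "",
    threshold: float = 0.8,
    block: int = 512,
) -> LoopClusterSet:
    """Greedy centroid clustering of (sequence, read count) items."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    agg: dict[str, int] = {}
    for seq, count in items:
        agg[seq] = agg.get(seq, 0) + count
    if not agg:
        raise ValueError("no sequences to cluster")
    seqs = sorted(agg, key=lambda s: (-agg[s], s))
    counts = np.stack([_count_vector(s) for s in seqs])
    lengths = counts.sum(axis=1)

    clusters: list[Cluster] = []
    cent_idx: list[int] = []  # indices into seqs, in creation order

    count_tuples = [tuple(int(x) for x in counts[i]) for i in range(len(seqs))]

    for lo in range(0, len(seqs), block):
        hi = min(lo + block, len(seqs))
        n_ext = len(cent_idx)
        passing: dict[int, list[int]] = {}
        if n_ext:
            # exact match-count upper bound from composition, then batch DP
            # verification of the surviving pairs
            d = cdist(counts[lo:hi], counts[cent_idx], metric="cityblock")
            ub_matches = (lengths[lo:hi, None] + lengths[cent_idx][None, :] - d) / 2.0
            maxlen = np.maximum(lengths[lo:hi, None], lengths[cent_idx][None, :])
            rows_e, cols_e = np.nonzero(ub_matches / maxlen >= threshold - 1e-12)
            if rows_e.size:
                idents = _batch_identity(
                    [(seqs[lo + r], seqs[cent_idx[k]]) for r, k in zip(rows_e, cols_e)]
                )
                for r, k, ok in zip(rows_e, cols_e, idents >= threshold - 1e-12):
                    if ok:
                        passing.setdefault(int(r), []).append(int(k))
        for row, i in enumerate(range(lo, hi)):
            seq = seqs[i]
            hits = passing.get(row, [])
            joined = False
            if hits:
                clusters[hits[0]].members.append((seq, agg[seq]))
                joined = True
            else:
                # centroids founded earlier within this block
                ca, la_ = count_tuples[i], lengths[i]
                for k in range(n_ext, len(cent_idx)):
                    cb, lb_ = count_tuples[cent_idx[k]], lengths[cent_idx[k]]
                    ub = (la_ + lb_ - sum(abs(x - y) for x, y in zip(ca, cb))) / 2.0
                    if ub / max(la_, lb_) < threshold - 1e-12:
                        continue
                    if pairwise_identity(seq, seqs[cent_idx[k]]) >= threshold - 1e-12:
                        clusters[k].members.append((seq, agg[seq]))
                        joined = True
                        break
            if not joined:
                clusters.append(Cluster(centroid=seq, members=[(seq, agg[seq])]))
                cent_idx.append(i)
    return LoopClusterSet(
        loop_id=loop_id, identity_threshold=threshold, clusters=clusters
    )


# ---------------------------------------------------------------------------
# Weighted sitewise counts and frequency matrices
# ---------------------------------------------------------------------------

def weighted_sitewise_counts(
    cluster_set: LoopClusterSet,
    design: LibraryDesign,
    exponent: float = 0.5,
    mode: str = "within_cluster_counts",
) -> dict[str, dict[str, float]]:
    """Aggregate per-site amino-acid weights across clusters.

    ``within_cluster_counts`` (default): within each cluster the raw per-site
    per-amino-acid read counts ``c`` are transformed to ``c**exponent`` and
    then summed across clusters.  ``cluster_weight``: each cluster contributes
    its internal per-site frequencies scaled by ``(cluster reads)**exponent``.
    """
    if mode not in ("within_cluster_counts", "cluster_weight"):
        raise ValueError(f"unknown weighting mode {mode!r}")
    totals: dict[str, dict[str, float]] = {}
    align_cache: dict[str, dict[str, str] | None] = {}
    n_unaligned = 0
    for cluster in cluster_set.clusters:
        local: dict[str, dict[str, float]] = {}
        cluster_reads = 0
        for seq, count in cluster.members:
            if seq not in align_cache:
                align_cache[seq] = align_loop(seq, cluster_set.loop_id, design)
            site_map = align_cache[seq]
            if site_map is None:
                n_unaligned += 1
                continue
            cluster_reads += count
            for site, aa in site_map.items():
                local.setdefault(site, {})
                local[site][aa] = local[site].get(aa, 0.0) + count
        if not local:
            continue
        for site, by_aa in local.items():
            out = totals.setdefault(site, {})
            if mode == "within_cluster_counts":
                for aa, c in by_aa.items():
                    out[aa] = out.get(aa, 0.0) + c ** exponent
            else:
                site_total = sum(by_aa.values())
                w = cluster_reads ** exponent
                for aa, c in by_aa.items():
                    out[aa] = out.get(aa, 0.0) + w * c / site_total
    if n_unaligned:
        warnings.warn(f"{n_unaligned} cluster members could not be aligned")
    return totals


def singleton_clusters(
    items: list[tuple[str, int]], loop_id: str = ""
) -> LoopClusterSet:
    """Every unique sequence its own cluster (the unweighted-pipeline input)."""
    agg: dict[str, int] = {}
    for seq, count in items:
        agg[seq] = agg.get(seq, 0) + count
    clusters = [
        Cluster(centroid=s, members=[(s, c)]) for s, c in sorted(agg.items())
    ]
    return LoopClusterSet(loop_id=loop_id, identity_threshold=1.0, clusters=clusters)


@dataclass
class FrequencyMatrix:
    """Sites x 20 amino-acid fractions with per-site effective weights.

    Rows with positive effective weight are probability vectors; rows with
    zero weight correspond to sites never observed (e.g. deleted positions).
    """

    freqs: pd.DataFrame
    weight: pd.Series

    def __post_init__(self) -> None:
        if list(self.freqs.columns) != list(AA20):
            raise ValueError("frequency matrix columns must be the 20 amino acids")
        active = self.weight > 0
        sums = self.freqs.loc[active].sum(axis=1)
        if len(sums) and not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("active frequency rows must sum to 1")
        if (self.freqs.values < -1e-12).any():
            raise ValueError("negative frequencies")

    @property
    def sites(self) -> list[str]:
        return list(self.freqs.index)

    def to_tsv(self, path) -> None:
        out = self.freqs.copy()
        out.insert(0, "effective_weight", self.weight)
        out.to_csv(path, sep="\t", index_label="site")

    @classmethod
    def from_tsv(cls, path) -> "FrequencyMatrix":
        df = pd.read_csv(path, sep="\t", index_col="site")
        weight = df.pop("effective_weight")
        return cls(freqs=df[list(AA20)], weight=weight)


def frequency_matrix(
    weighted_counts: dict[str, dict[str, float]],
    sites: list[str] | None = None,
) -> FrequencyMatrix:
    """Normalize per-site weighted counts into a :class:`FrequencyMatrix`.

    ``sites`` optionally fixes the row set; sites without observations get
    effective weight 0 and an all-zero row.
    """
    if sites is None:
        sites = sorted(weighted_counts, key=site_sort_key)
    data = np.zeros((len(sites), len(AA20)))
    weight = np.zeros(len(sites))
    for r, site in enumerate(sites):
        by_aa = weighted_counts.get(site, {})
        total = sum(by_aa.values())
        if total <= 0:
            continue
        weight[r] = total
        for aa, c in by_aa.items():
            if c < 0:
                raise ValueError("negative weighted count")
            data[r, _AA_INDEX[aa]] = c / total
    df = pd.DataFrame(data, index=sites, columns=list(AA20))
    return FrequencyMatrix(freqs=df, weight=pd.Series(weight, index=sites))


def frequency_delta(binder: FrequencyMatrix, naive: FrequencyMatrix) -> pd.DataFrame:
    """Binder minus naive sitewise frequencies (rows sum to ~0)."""
    if set(binder.sites) != set(naive.sites):
        raise ValueError("frequency matrices cover different site sets")
    return binder.freqs - naive.freqs.loc[binder.sites]


# ---------------------------------------------------------------------------
# Convenience plumbing
# ---------------------------------------------------------------------------

def loop_items(records, loop_id: str) -> list[tuple[str, int]]:
    """(loop sequence, read count) items of full-length, aligned clones."""
    out = []
    for rec in records:
        if rec.classification == "full_length" and loop_id in rec.site_maps:
            out.append((rec.loops[loop_id], rec.count))
    return out


def population_frequency_matrix(
    records,
    design: LibraryDesign,
    cluster: bool = True,
    threshold: float = 0.8,
    exponent: float = 0.5,
    sites: list[str] | None = None,
) -> FrequencyMatrix:
    """Whole-repertoire sitewise matrix: per-loop clustering + weighting.

    With ``cluster=False`` every unique loop sequence is its own cluster and
    the exponent is forced to 1 (plain counting) -- the naive-population
    pipeline.
    """
    from .library_model import LOOP_IDS

    totals: dict[str, dict[str, float]] = {}
    for loop_id in LOOP_IDS:
        items = loop_items(records, loop_id)
        if not items:
            continue
        if cluster:
            cs = cluster_loops(items, loop_id, threshold=threshold)
            wc = weighted_sitewise_counts(cs, design, exponent=exponent)
        else:
            cs = singleton_clusters(items, loop_id)
            wc = weighted_sitewise_counts(cs, design, exponent=1.0)
        for site, by_aa in wc.items():
            out = totals.setdefault(site, {})
            for aa, w in by_aa.items():
                out[aa] = out.get(aa, 0.0) + w
    return frequency_matrix(
        totals, sites=sites or design.all_site_labels()
    )


def design_frequency_matrix(
    design: LibraryDesign, include_stop: bool = False
) -> FrequencyMatrix:
    """Theoretical sitewise matrix of a design (stop-conditioned by default)."""
    from .library_model import theoretical_site_distribution

    counts = {}
    for site in design.all_site_labels():
        dist = theoretical_site_distribution(
            design, site, include_stop=include_stop
        )
        counts[site] = {a: p for a, p in dist.probs.items() if a != "*"}
    return frequency_matrix(counts)
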