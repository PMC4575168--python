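"""Sequence probability model and leave-one-out cross-validated log-odds.

Sequences are scored under a sitewise-independence model: the log10
probability of a loop sequence is the log length-class prior plus the sum of
log sitewise frequencies (floored at ``FLOOR`` to keep structural zeros
finite).  The evolvability analysis holds out one sequence cluster at a time,
rebuilds the evolved frequency model from the remaining clusters with the
same weighting pipeline, and scores every held-out sequence as
``log10(P_evolved / P_naive)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .library_model import LibraryDesign, theoretical_site_distribution
from .repertoire_core import (
    FrequencyMatrix,
    LoopClusterSet,
    frequency_matrix,
    weighted_sitewise_counts,
)
from .seq_processing import align_loop

FLOOR = 1e-4


@dataclass
class LogOddsRecord:
    sequence: str
    log_odds: float                      # log10(P_evolved / P_naive)
    sitewise_terms: dict[str, float]     # site -> log10 frequency ratio
    length_term: float
    count: int = 1

    def __post_init__(self) -> None:
        total = self.length_term + sum(self.sitewise_terms.values())
        if abs(total - self.log_odds) > 1e-9:
            raise ValueError("log-odds decomposition identity violated")


@dataclass
class LoocvSummary:
    records: list[LogOddsRecord]
    fraction_positive: float
    positive_negative_ratio: float
    median_log_odds: float
    median_percent_increase: float       # 10**median - 1, as a percent


def sequence_log_probability(
    loop_seq: str,
    loop_id: str,
    fm: FrequencyMatrix,
    length_priors: dict[int, float] | None,
    design: LibraryDesign,
    floor: float = FLOOR,
) -> tuple[float, dict[str, float], float]:
    """log10 probability of one loop sequence under a sitewise model.

    Returns (total, per-site log10 terms, length log10 term).  Sites absent
    from the sequence's length class contribute nothing.
    """
    if not (0.0 < floor <= 0.01):
        raise ValueError("floor must be in (0, 0.01]")
    site_map = align_loop(loop_seq, loop_id, design)
    if site_map is None:
        raise ValueError(f"loop {loop_seq!r} matches no design length variant")
    if length_priors is None:
        length_term = 0.0
    else:
        p_len = length_priors.get(len(loop_seq), 0.0)
        length_term = float(np.log10(max(p_len, floor)))
    site_terms = {}
    for site, aa in site_map.items():
        f = float(fm.freqs.loc[site, aa]) if site in fm.freqs.index else 0.0
        site_terms[site] = float(np.log10(max(f, floor)))
    return length_term + sum(site_terms.values()), site_terms, length_term


def design_length_priors(design: LibraryDesign, loop_id: str) -> dict[int, float]:
    """Pool-weighted theoretical loop length distribution of a design."""
    priors: dict[int, float] = {}
    for sub in design.sublibraries:
        for var in sub.loops[loop_id].length_variants:
            n = len(var.sites)
            priors[n] = priors.get(n, 0.0) + sub.weight * var.weight
    return priors


def empirical_length_priors(clusters: LoopClusterSet) -> dict[int, float]:
    counts: dict[int, int] = {}
    for cl in clusters.clusters:
        for seq, c in cl.members:
            counts[len(seq)] = counts.get(len(seq), 0) + c
    total = sum(counts.values())
    return {n: c / total for n, c in counts.items()}


def loocv_log_odds(
    binder_clusters: LoopClusterSet,
    design: LibraryDesign,
    naive_fm: FrequencyMatrix | None = None,
    exponent: float = 0.5,
    weighting_mode: str = "within_cluster_counts",
    floor: float = FLOOR,
    use_length_prior: bool = True,
) -> LoocvSummary:
    """Exhaustive leave-one-out log-odds over sequence clusters.

    For each held-out cluster the evolved frequency matrix is rebuilt from the
    remaining clusters (same weighting pipeline, implemented by subtracting
    the held-out cluster's weighted contribution), and every held-out
    sequence is scored ``log10(P_evolved / P_naive)``.  Naive probabilities
    come from the design's exact theoretical distributions unless an
    empirical ``naive_fm`` is supplied.
    """
    if len(binder_clusters.clusters) < 2:
        raise ValueError("LOOCV needs at least 2 clusters")
    loop_id = binder_clusters.loop_id
    if naive_fm is None:
        from .repertoire_core import design_frequency_matrix

        naive_fm = design_frequency_matrix(design)
    naive_len = design_length_priors(design, loop_id) if use_length_prior else None

    # Total weighted counts and per-cluster contributions (for subtraction).
    def cluster_contrib(cluster) -> dict[str, dict[str, float]]:
        single = LoopClusterSet(loop_id, binder_clusters.identity_threshold, [cluster])
        return weighted_sitewise_counts(
            single, design, exponent=exponent, mode=weighting_mode
        )

    contribs = [cluster_contrib(cl) for cl in binder_clusters.clusters]
    totals: dict[str, dict[str, float]] = {}
    for contrib in contribs:
        for site, by_aa in contrib.items():
            out = totals.setdefault(site, {})
            for aa, w in by_aa.items():
                out[aa] = out.get(aa, 0.0) + w

    # Length-class weighted counts, same exponent on within-cluster counts.
    len_contribs = []
    for cl in binder_clusters.clusters:
        by_len: dict[int, float] = {}
        for seq, c in cl.members:
            by_len[len(seq)] = by_len.get(len(seq), 0.0) + c
        len_contribs.append({n: c ** exponent for n, c in by_len.items()})
    len_totals: dict[int, float] = {}
    for lc in len_contribs:
        for n, w in lc.items():
            len_totals[n] = len_totals.get(n, 0.0) + w

    all_sites = sorted(totals)
    records: list[LogOddsRecord] = []
    for cl, contrib, len_contrib in zip(
        binder_clusters.clusters, contribs, len_contribs
    ):
        held_out_counts = {
            site: {
                aa: totals[site][aa] - contrib.get(site, {}).get(aa, 0.0)
                for aa in totals[site]
            }
            for site in totals
        }
        train_fm = frequency_matrix(held_out_counts, sites=all_sites)
        if use_length_prior:
            train_len_counts = {
                n: len_totals[n] - len_contrib.get(n, 0.0) for n in len_totals
            }
            denom = sum(train_len_counts.values())
            train_len = (
                {n: c / denom for n, c in train_len_counts.items()}
                if denom > 0
                else {}
            )
        else:
            train_len = None
        for seq, count in cl.members:
            try:
                ev, ev_sites, ev_len = sequence_log_probability(
                    seq, loop_id, train_fm, train_len, design, floor
                )
                na, na_sites, na_len = sequence_log_probability(
                    seq, loop_id, naive_fm, naive_len, design, floor
                )
            except ValueError:
                continue
            records.append(
                LogOddsRecord(
                    sequence=seq,
                    log_odds=ev - na,
                    sitewise_terms={
                        s: ev_sites[s] - na_sites[s] for s in ev_sites
                    },
                    length_term=ev_len - na_len,
                    count=count,
                )
            )
    if not records:
        raise ValueError("no scorable sequences")
    scores = np.array([r.log_odds for r in records])
    n_pos = int((scores > 0).sum())
    n_neg = int((scores < 0).sum())
    med = float(np.median(scores))
    return LoocvSummary(
        records=records,
        fraction_positive=n_pos / len(scores),
        positive_negative_ratio=n_pos / n_neg if n_neg else float("inf"),
        median_log_odds=med,
        median_percent_increase=(10.0 ** med - 1.0) * 100.0,
    )


def sitewise_log_odds(records: list[LogOddsRecord]) -> "pd.DataFrame":
    """Per-site mean log-odds term, also as percent likelihood change."""
    import pandas as pd

    from .alphabet import site_sort_key

    if not records:
        raise ValueError("no records")
    acc: dict[str, list[float]] = {}
    for r in records:
        for site, term in r.sitewise_terms.items():
            acc.setdefault(site, []).append(term)
    rows = []
    for site in sorted(acc, key=site_sort_key):
        terms = np.array(acc[site])
        rows.append(
            {
                "site": site,
                "n": len(terms),
                "mean_term": float(terms.mean()),
                "percent_change": (10.0 ** float(terms.mean()) - 1.0) * 100.0,
            }
        )
    return pd.DataFrame(rows)
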