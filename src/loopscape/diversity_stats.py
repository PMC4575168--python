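"""Entropy landscapes, enrichment summaries and significance testing.

Entropy is reported in log base 2 by default, so a uniform 20-amino-acid
site scores ``log2(20) = 4.32`` and a conserved site scores 0.  The base is
configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import AA20
from .library_model import LOOP_IDS, LibraryDesign
from .repertoire_core import FrequencyMatrix


@dataclass
class EntropyProfile:
    entropy: pd.Series  # site -> H
    population: str = ""
    base: float = 2.0


@dataclass
class EntropyDelta:
    delta: pd.Series
    n_constrained: int      # sites with negative entropy change
    mean_change: float


def shannon_entropy(
    fm: FrequencyMatrix, population: str = "", base: float = 2.0
) -> EntropyProfile:
    """Per-site Shannon entropy, -sum p*log(p) with 0*log(0) := 0.

    Sites with zero effective weight are omitted.
    """
    active = fm.weight > 0
    p = fm.freqs.loc[active].values
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1) / np.log(base)
    h = np.maximum(h, 0.0)  # clip -0.0 from conserved rows
    return EntropyProfile(
        entropy=pd.Series(h, index=fm.freqs.index[active]),
        population=population,
        base=base,
    )


def entropy_delta(binder: EntropyProfile, naive: EntropyProfile) -> EntropyDelta:
    """Binder minus naive entropy per site, with constraint summary."""
    if set(binder.entropy.index) != set(naive.entropy.index):
        raise ValueError("entropy profiles cover different site sets")
    if binder.base != naive.base:
        raise ValueError("entropy profiles use different log bases")
    d = binder.entropy - naive.entropy.loc[binder.entropy.index]
    return EntropyDelta(
        delta=d, n_constrained=int((d < 0).sum()), mean_change=float(d.mean())
    )


# ---------------------------------------------------------------------------
# Significance testing
# ---------------------------------------------------------------------------

def significance_test(
    replicates_a: list[FrequencyMatrix],
    replicates_b: list[FrequencyMatrix],
    alpha: float = 0.005,
) -> pd.DataFrame:
    """Two-sample t-test per (site, amino acid), Bonferroni-corrected.

    Each replicate is one frequency matrix (e.g. one binding campaign).  The
    familywise correction uses the adjusted threshold ``alpha / m`` over the
    ``m`` tests performed; both the raw p-value and the adjusted significance
    flag are reported.  With fewer than two replicates per group the flags are
    undefined (NaN) and a warning is issued.
    """
    sites = replicates_a[0].sites
    for fm in replicates_a + replicates_b:
        if fm.sites != sites:
            raise ValueError("replicates cover different site sets")
    rows = []
    undefined = len(replicates_a) < 2 or len(replicates_b) < 2
    if undefined:
        warnings.warn("fewer than 2 replicates per group: flags are undefined")
    a_stack = np.stack([fm.freqs.values for fm in replicates_a])
    b_stack = np.stack([fm.freqs.values for fm in replicates_b])
    m = len(sites) * len(AA20)
    for si, site in enumerate(sites):
        for ai, aa in enumerate(AA20):
            a = a_stack[:, si, ai]
            b = b_stack[:, si, ai]
            if undefined:
                p = np.nan
            else:
                with np.errstate(invalid="ignore", divide="ignore"):
                    _, p = stats.ttest_ind(a, b)
                if np.isnan(p):  # zero variance in both groups
                    p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
            rows.append(
                {
                    "site": site,
                    "aa": aa,
                    "mean_a": a.mean(),
                    "mean_b": b.mean(),
                    "delta": b.mean() - a.mean(),
                    "p_value": p,
                    "significant": (p < alpha / m) if not undefined else np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Loop lengths, cysteines, framework mutations
# ---------------------------------------------------------------------------

def loop_length_distribution(records) -> pd.DataFrame:
    """Read-weighted loop length frequencies of aligned full-length clones."""
    counts: dict[str, dict[int, int]] = {lid: {} for lid in LOOP_IDS}
    for rec in records:
        if rec.classification != "full_length":
            continue
        for lid in LOOP_IDS:
            if lid in rec.site_maps:
                n = len(rec.loops[lid])
                counts[lid][n] = counts[lid].get(n, 0) + rec.count
    rows = []
    for lid in LOOP_IDS:
        total = sum(counts[lid].values())
        for n, c in sorted(counts[lid].items()):
            rows.append(
                {"loop": lid, "length": n, "count": c, "frequency": c / total}
            )
    return pd.DataFrame(rows)


def cysteine_profile(naive_records, binder_records, normalize: str = "pairs"):
    """Cysteine count histograms and the 2-cysteine site-pair delta matrix.

    ``normalize='pairs'`` (default) normalizes the pair matrix over clones
    with exactly two cysteines; ``'population'`` normalizes over all clones.
    Returns (histogram DataFrame, pair-delta DataFrame).
    """

    def hist_and_pairs(records):
        hist: dict[int, int] = {}
        pair_counts: dict[tuple[str, str], int] = {}
        total = 0
        two_cys = 0
        for rec in records:
            if rec.classification != "full_length" or not rec.site_maps:
                continue
            cys_sites = [
                site
                for sm in rec.site_maps.values()
                for site, aa in sm.items()
                if aa == "C"
            ]
            total += rec.count
            hist[len(cys_sites)] = hist.get(len(cys_sites), 0) + rec.count
            if len(cys_sites) == 2:
                two_cys += rec.count
                key = tuple(sorted(cys_sites))
                pair_counts[key] = pair_counts.get(key, 0) + rec.count
        return hist, pair_counts, total, two_cys

    h_n, p_n, tot_n, two_n = hist_and_pairs(naive_records)
    h_b, p_b, tot_b, two_b = hist_and_pairs(binder_records)

    max_c = max([*h_n, *h_b, 0])
    hist = pd.DataFrame(
        {
            "n_cys": range(max_c + 1),
            "naive": [h_n.get(i, 0) / tot_n if tot_n else 0.0 for i in range(max_c + 1)],
            "binder": [h_b.get(i, 0) / tot_b if tot_b else 0.0 for i in range(max_c + 1)],
        }
    )

    all_sites = sorted(
        {s for k in (*p_n, *p_b) for s in k},
    )
    delta = pd.DataFrame(0.0, index=all_sites, columns=all_sites)
    for pairs, denom_pairs, denom_pop, sign in (
        (p_n, two_n, tot_n, -1.0),
        (p_b, two_b, tot_b, 1.0),
    ):
        denom = denom_pairs if normalize == "pairs" else denom_pop
        if denom == 0:
            continue
        for (s1, s2), c in pairs.items():
            delta.loc[s1, s2] += sign * c / denom
            delta.loc[s2, s1] += sign * c / denom
    return hist, delta


def framework_enrichment(
    naive_records, binder_records, design: LibraryDesign
) -> pd.DataFrame:
    """Non-reference residue frequencies at framework sites, naive vs binder.

    Sorted by binder-minus-naive enrichment, descending.
    """
    from .seq_processing import framework_site_labels

    labels = framework_site_labels(design)

    def site_counts(records):
        counts: dict[tuple[str, str], int] = {}
        total = 0
        for rec in records:
            if rec.classification != "full_length" or rec.framework_protein is None:
                continue
            if len(rec.framework_protein) != len(labels):
                continue
            total += rec.count
            for label, aa in zip(labels, rec.framework_protein):
                if aa != label[0]:
                    counts[(label, aa)] = counts.get((label, aa), 0) + rec.count
        return counts, total

    n_counts, n_total = site_counts(naive_records)
    b_counts, b_total = site_counts(binder_records)
    keys = sorted(set(n_counts) | set(b_counts))
    rows = []
    for label, aa in keys:
        nf = n_counts.get((label, aa), 0) / n_total if n_total else 0.0
        bf = b_counts.get((label, aa), 0) / b_total if b_total else 0.0
        rows.append(
            {
                "site": label,
                "mutation": f"{label[0]}{label[1:]}{aa}",
                "residue": aa,
                "naive_freq": nf,
                "binder_freq": bf,
                "enrichment": bf - nf,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["site", "mutation", "residue", "naive_freq", "binder_freq", "enrichment"],
    )
    return df.sort_values("enrichment", ascending=False).reset_index(drop=True)


def wild_type_conservation(
    fm: FrequencyMatrix, design: LibraryDesign
) -> pd.Series:
    """Per-site frequency of the reference (wild-type) residue.

    Insertion-coded sites without a reference residue are omitted.
    """
    out = {}
    for site in fm.sites:
        wt = design.wild_type_residue(site)
        if wt is None or fm.weight[site] <= 0:
            continue
        out[site] = float(fm.freqs.loc[site, wt])
    return pd.Series(out)
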