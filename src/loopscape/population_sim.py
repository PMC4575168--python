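"""Synthetic population generator with planted, recoverable ground truth.

Samples naive DNA populations from a :class:`~loopscape.library_model.LibraryDesign`
(degenerate codons are sampled at the nucleotide level, so stop codons arise
naturally), injects sequencing/synthesis errors, and applies a multiplicative
sitewise selection model to produce "binder" populations whose enrichments are
known exactly.  Every downstream analysis stage can therefore be tested by
parameter recovery.

Randomness contract: each operation takes a seed (or ``numpy.random.Generator``)
and is byte-for-byte deterministic given identical inputs and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .alphabet import CODON_TABLE, PREFERRED_CODON, STOP
from .library_model import LOOP_IDS, LengthVariant, LibraryDesign, SiteSpec


@dataclass
class CloneTruth:
    """Ground-truth record of how a simulated clone was generated."""

    sublibrary: dict[str, int]          # loop id -> sublibrary row index
    loop_lengths: dict[str, int]        # loop id -> number of diversified sites
    residues: dict[str, str]            # site label -> sampled residue ('*' = stop)
    has_stop: bool = False
    injected_subs: int = 0
    injected_indels: int = 0


@dataclass
class SimulatedClone:
    dna: str
    truth: CloneTruth | None = None
    read_count: int = 1

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")


@dataclass
class Population:
    clones: list[SimulatedClone]
    label: str = "naive"

    def __post_init__(self) -> None:
        if any(c.read_count < 1 for c in self.clones):
            raise ValueError("clone counts must be >= 1")

    @property
    def total_count(self) -> int:
        return sum(c.read_count for c in self.clones)

    def __len__(self) -> int:
        return len(self.clones)


@dataclass(frozen=True)
class SelectionModel:
    """Independent-site multiplicative (log-additive) fitness model.

    ``site_scores[site][aa]`` and ``length_scores[loop][length]`` are
    log-fitness contributions; a clone's fitness is
    ``exp(stringency * sum of applicable scores)``.  Clones carrying stop
    codons or injected indels are never selected.
    """

    site_scores: dict[str, dict[str, float]] = field(default_factory=dict)
    length_scores: dict[str, dict[int, float]] = field(default_factory=dict)
    rounds: int = 1
    stringency: float = 1.0

    def __post_init__(self) -> None:
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        for site, by_aa in self.site_scores.items():
            for aa, v in by_aa.items():
                if not math.isfinite(v):
                    raise ValueError(f"non-finite score at {site}/{aa}")
        for loop, by_len in self.length_scores.items():
            for n, v in by_len.items():
                if not math.isfinite(v):
                    raise ValueError(f"non-finite length score at {loop}/{n}")

    def log_fitness(self, truth: CloneTruth) -> float:
        if truth.has_stop or truth.injected_indels:
            return -math.inf
        total = 0.0
        for site, aa in truth.residues.items():
            total += self.site_scores.get(site, {}).get(aa, 0.0)
        for loop, n in truth.loop_lengths.items():
            total += self.length_scores.get(loop, {}).get(n, 0.0)
        return total


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

_NT = np.array(list("ACGT"))
_CODON64 = np.array(
    [CODON_TABLE[a + b + c] for a in "ACGT" for b in "ACGT" for c in "ACGT"]
)


def _sample_variant_sites(
    var: LengthVariant, m: int, rng: np.random.Generator
) -> tuple[list[str], dict[str, np.ndarray]]:
    """Vectorized draw of ``m`` clones from one length variant.

    Returns per-clone loop DNA strings and a site-label -> residue-array map.
    """
    codon_cols: list[np.ndarray] = []
    residues: dict[str, np.ndarray] = {}
    for site in var.sites:
        if site.kind == "degenerate_codon":
            idx = np.empty((m, 3), dtype=np.int64)
            for pos in range(3):
                p = np.array([site.mix.p(pos, nt) for nt in "ACGT"])
                idx[:, pos] = rng.choice(4, size=m, p=p / p.sum())
            flat = idx[:, 0] * 16 + idx[:, 1] * 4 + idx[:, 2]
            residues[site.site_label] = _CODON64[flat]
            codons = np.char.add(
                np.char.add(_NT[idx[:, 0]], _NT[idx[:, 1]]), _NT[idx[:, 2]]
            )
        else:
            aas = sorted(site.aa_probs)
            p = np.array([site.aa_probs[a] for a in aas])
            aa_idx = rng.choice(len(aas), size=m, p=p / p.sum())
            aa_arr = np.array(aas)[aa_idx]
            residues[site.site_label] = aa_arr
            codons = np.array([PREFERRED_CODON[a] for a in aas])[aa_idx]
        codon_cols.append(codons)
    if codon_cols:
        dna = codon_cols[0]
        for col in codon_cols[1:]:
            dna = np.char.add(dna, col)
        return list(dna), residues
    return [""] * m, residues


def _framework_segments(design: LibraryDesign) -> list[str]:
    """Framework DNA split around the diversified regions, in loop order."""
    fw = design.framework
    segs = []
    pos = 0
    for loop_id in LOOP_IDS:
        a, b = fw.regions[loop_id]
        segs.append(fw.dna[pos * 3:a * 3])
        pos = b
    segs.append(fw.dna[pos * 3:])
    return segs


def sample_population(
    design: LibraryDesign, n: int, seed, label: str = "naive"
) -> Population:
    """Draw ``n`` i.i.d. clones from a design.

    Per clone: sublibrary rows by pool weight (independently per loop under
    ``independent`` pooling, one shared row under ``row_matched``), loop length
    by variant weight, residues per site spec.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    segs = _framework_segments(design)
    pool_w = np.array([s.weight for s in design.sublibraries])
    pool_w = pool_w / pool_w.sum()
    n_sub = len(design.sublibraries)

    # Per-loop sublibrary assignment for every clone.
    if design.pooling == "row_matched":
        shared = rng.choice(n_sub, size=n, p=pool_w)
        row_of = {loop_id: shared for loop_id in LOOP_IDS}
    else:
        row_of = {
            loop_id: rng.choice(n_sub, size=n, p=pool_w) for loop_id in LOOP_IDS
        }

    loop_dna = {loop_id: [""] * n for loop_id in LOOP_IDS}
    loop_len = {loop_id: np.zeros(n, dtype=np.int64) for loop_id in LOOP_IDS}
    residues: list[dict[str, str]] = [{} for _ in range(n)]
    has_stop = np.zeros(n, dtype=bool)

    for loop_id in LOOP_IDS:
        rows = row_of[loop_id]
        for r in range(n_sub):
            idx_r = np.flatnonzero(rows == r)
            if idx_r.size == 0:
                continue
            loop = design.sublibraries[r].loops[loop_id]
            w = np.array([v.weight for v in loop.length_variants])
            var_idx = rng.choice(len(w), size=idx_r.size, p=w / w.sum())
            for k, var in enumerate(loop.length_variants):
                idx = idx_r[var_idx == k]
                if idx.size == 0:
                    continue
                dna_list, res = _sample_variant_sites(var, idx.size, rng)
                loop_len[loop_id][idx] = len(var.sites)
                for j, i in enumerate(idx):
                    loop_dna[loop_id][i] = dna_list[j]
                for label_, arr in res.items():
                    stops = arr == STOP
                    if stops.any():
                        has_stop[idx[stops]] = True
                    for j, i in enumerate(idx):
                        residues[i][label_] = arr[j]

    clones = []
    for i in range(n):
        dna = (
            segs[0] + loop_dna["BC"][i] + segs[1] + loop_dna["DE"][i]
            + segs[2] + loop_dna["FG"][i] + segs[3]
        )
        clones.append(
            SimulatedClone(
                dna=dna,
                truth=CloneTruth(
                    sublibrary={lid: int(row_of[lid][i]) for lid in LOOP_IDS},
                    loop_lengths={lid: int(loop_len[lid][i]) for lid in LOOP_IDS},
                    residues=residues[i],
                    has_stop=bool(has_stop[i]),
                ),
            )
        )
    return Population(clones=clones, label=label)


# ---------------------------------------------------------------------------
# Error injection
# ---------------------------------------------------------------------------

def inject_errors(
    pop: Population, sub_rate: float, indel_rate: float, seed
) -> Population:
    """Apply per-base substitutions and single-base indels to each clone.

    Rates must lie in [0, 0.2].  Injected events are recorded in the clone
    truth so downstream classification can be checked against ground truth.
    """
    for name, rate in (("sub_rate", sub_rate), ("indel_rate", indel_rate)):
        if not (0.0 <= rate <= 0.2):
            raise ValueError(f"{name} must be in [0, 0.2], got {rate}")
    rng = _as_rng(seed)
    out = []
    for clone in pop.clones:
        seq = list(clone.dna)
        n_sub = int(rng.binomial(len(seq), sub_rate)) if sub_rate else 0
        for i in rng.choice(len(seq), size=n_sub, replace=False) if n_sub else []:
            alternatives = [b for b in "ACGT" if b != seq[i]]
            seq[i] = alternatives[int(rng.integers(3))]
        n_indel = int(rng.binomial(len(seq), indel_rate)) if indel_rate else 0
        for _ in range(n_indel):
            pos = int(rng.integers(len(seq)))
            if rng.random() < 0.5:
                del seq[pos]
            else:
                seq.insert(pos, "ACGT"[int(rng.integers(4))])
        truth = clone.truth
        if truth is not None and (n_sub or n_indel):
            truth = replace(
                truth,
                injected_subs=truth.injected_subs + n_sub,
                injected_indels=truth.injected_indels + n_indel,
            )
        out.append(SimulatedClone("".join(seq), truth, clone.read_count))
    return Population(clones=out, label=pop.label)


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def simulate_selection(
    pop: Population, model: SelectionModel, seed, label: str = "binder"
) -> Population:
    """Resample clone counts under the planted fitness model.

    Each round draws a multinomial with probabilities proportional to
    ``count * exp(stringency * log-fitness)``; the total read count is
    preserved exactly.
    """
    if not pop.clones:
        raise ValueError("empty population")
    rng = _as_rng(seed)
    counts = np.array([c.read_count for c in pop.clones], dtype=np.int64)
    total = int(counts.sum())
    log_fit = np.array(
        [
            model.stringency * model.log_fitness(c.truth)
            if c.truth is not None
            else 0.0
            for c in pop.clones
        ]
    )
    if np.all(np.isneginf(log_fit)):
        raise ValueError("no selectable clones: all have -inf fitness")
    for _ in range(model.rounds):
        with np.errstate(invalid="ignore"):
            logw = np.where(counts > 0, np.log(np.maximum(counts, 1)) + log_fit, -np.inf)
        finite = np.isfinite(logw)
        if not finite.any():
            raise ValueError("no selectable clones: all have -inf fitness")
        logw = logw - logw[finite].max()
        w = np.where(finite, np.exp(logw), 0.0)
        p = w / w.sum()
        counts = rng.multinomial(total, p)
    out = [
        SimulatedClone(c.dna, c.truth, int(k))
        for c, k in zip(pop.clones, counts)
        if k > 0
    ]
    return Population(clones=out, label=label)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_fasta(pop: Population, path) -> None:
    """Write one record per clone; the id encodes the read count."""
    with open(path, "w") as fh:
        for i, clone in enumerate(pop.clones):
            fh.write(f">clone_{i}|count={clone.read_count}\n{clone.dna}\n")


def write_fastq(pop: Population, path, quality: str = "I") -> None:
    """Write reads with uniform quality; counts expand to repeated records."""
    with open(path, "w") as fh:
        for i, clone in enumerate(pop.clones):
            for j in range(clone.read_count):
                fh.write(
                    f"@clone_{i}_{j}\n{clone.dna}\n+\n{quality * len(clone.dna)}\n"
                )


def write_truth_table(pop: Population, path) -> None:
    with open(path, "w") as fh:
        fh.write("clone\tcount\tsublibrary\tloop_lengths\thas_stop\tindels\tresidues\n")
        for i, clone in enumerate(pop.clones):
            t = clone.truth
            if t is None:
                continue
            res = ",".join(f"{k}:{v}" for k, v in sorted(t.residues.items()))
            subs = ",".join(f"{k}:{v}" for k, v in sorted(t.sublibrary.items()))
            lens = ",".join(f"{k}:{v}" for k, v in sorted(t.loop_lengths.items()))
            fh.write(
                f"clone_{i}\t{clone.read_count}\t{subs}\t{lens}\t"
                f"{int(t.has_stop)}\t{t.injected_indels}\t{res}\n"
            )
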