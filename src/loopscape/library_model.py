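"""Sitewise combinatorial-library designs and exact degenerate-codon math.

A :class:`LibraryDesign` describes a loop-diversified protein library: a
conserved framework, three diversified loop regions (BC, DE, FG), one or more
sublibraries per loop, and per-site amino-acid specifications that are either
explicit amino-acid sets or degenerate codons built from per-position
nucleotide mixtures.  The module computes exact theoretical amino-acid (and
stop) distributions for any designed site by enumerating all 64 codons.

Two designs are packaged (``gen1``, ``gen2``) and loadable by name via
:func:`load_design`.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .alphabet import (
    AA20,
    AA21,
    CODON_TABLE,
    NUCLEOTIDES,
    STOP,
    back_translate,
    site_sort_key,
    validate_aa,
)

_TOL = 1e-9

LOOP_IDS = ("BC", "DE", "FG")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AADistribution:
    """Probabilities over the 20 amino acids plus stop; sums to 1."""

    probs: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.probs) - set(AA21)
        if unknown:
            raise ValueError(f"unknown amino-acid letters: {sorted(unknown)}")
        if any(p < -_TOL for p in self.probs.values()):
            raise ValueError("negative probability in amino-acid distribution")
        if abs(sum(self.probs.values()) - 1.0) > _TOL:
            raise ValueError(
                f"amino-acid distribution sums to {sum(self.probs.values())!r}, not 1"
            )

    def __getitem__(self, aa: str) -> float:
        return self.probs.get(aa, 0.0)

    @property
    def stop(self) -> float:
        return self.probs.get(STOP, 0.0)

    def without_stop(self) -> "AADistribution":
        """Condition on not encoding a stop codon."""
        keep = {a: p for a, p in self.probs.items() if a != STOP}
        total = sum(keep.values())
        if total <= 0:
            raise ValueError("distribution is all stop; cannot condition")
        return AADistribution({a: p / total for a, p in keep.items()})

    def as_vector(self) -> list[float]:
        """Fractions over the canonical AA20 order (stop excluded)."""
        return [self.probs.get(a, 0.0) for a in AA20]


@dataclass(frozen=True)
class NucleotideMix:
    """Per-position nucleotide fractions of one degenerate codon.

    ``freqs`` holds three position maps (codon positions 1-3), each giving the
    fraction of A/C/G/T.  Each position must sum to 1.
    """

    freqs: tuple[dict[str, float], dict[str, float], dict[str, float]]

    def __post_init__(self) -> None:
        if len(self.freqs) != 3:
            raise ValueError("a codon mix needs exactly 3 positions")
        for i, pos in enumerate(self.freqs):
            if set(pos) - set(NUCLEOTIDES):
                raise ValueError(f"position {i + 1}: unknown nucleotide letters")
            if any(v < 0 for v in pos.values()):
                raise ValueError(f"position {i + 1}: negative nucleotide frequency")
            if abs(sum(pos.values()) - 1.0) > _TOL:
                raise ValueError(
                    f"position {i + 1} frequencies sum to {sum(pos.values())!r}, not 1"
                )

    def p(self, position: int, nt: str) -> float:
        return self.freqs[position].get(nt, 0.0)


@dataclass(frozen=True)
class SiteSpec:
    """Design of a single diversified site.

    ``kind`` is one of ``fixed_set`` (explicit amino-acid probabilities),
    ``conserved`` (a single amino acid), or ``degenerate_codon`` (nucleotide
    mixture; stops may arise).
    """

    site_label: str
    kind: str
    aa_probs: dict[str, float] | None = None
    mix: NucleotideMix | None = None
    mix_name: str | None = None

    def __post_init__(self) -> None:
        if self.kind in ("fixed_set", "conserved"):
            if not self.aa_probs:
                raise ValueError(f"{self.site_label}: {self.kind} site needs aa_probs")
            for aa in self.aa_probs:
                validate_aa(aa)
            if any(p < 0 for p in self.aa_probs.values()):
                raise ValueError(f"{self.site_label}: negative amino-acid probability")
            if abs(sum(self.aa_probs.values()) - 1.0) > _TOL:
                raise ValueError(f"{self.site_label}: aa_probs do not sum to 1")
            if self.kind == "conserved" and (
                len(self.aa_probs) != 1
                or abs(next(iter(self.aa_probs.values())) - 1.0) > _TOL
            ):
                raise ValueError(
                    f"{self.site_label}: conserved site must fix one amino acid"
                )
        elif self.kind == "degenerate_codon":
            if self.mix is None:
                raise ValueError(f"{self.site_label}: degenerate site needs a mix")
        else:
            raise ValueError(f"{self.site_label}: unknown site kind {self.kind!r}")

    def distribution(self) -> AADistribution:
        if self.kind == "degenerate_codon":
            return codon_aa_distribution(self.mix)
        return AADistribution(dict(self.aa_probs))


@dataclass(frozen=True)
class LengthVariant:
    sites: tuple[SiteSpec, ...]
    weight: float

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.site_label for s in self.sites)


@dataclass(frozen=True)
class LoopDesign:
    """One loop region of one sublibrary: length variants with prior weights."""

    loop_id: str
    anchor_sites: tuple[str, str]
    length_variants: tuple[LengthVariant, ...]

    def __post_init__(self) -> None:
        if self.loop_id not in LOOP_IDS:
            raise ValueError(f"unknown loop id {self.loop_id!r}")
        if not self.length_variants:
            raise ValueError(f"{self.loop_id}: no length variants")
        total = sum(v.weight for v in self.length_variants)
        if abs(total - 1.0) > _TOL:
            raise ValueError(f"{self.loop_id}: variant weights sum to {total!r}")
        lengths = [len(v.sites) for v in self.length_variants]
        if len(set(lengths)) != len(lengths):
            raise ValueError(f"{self.loop_id}: duplicate variant lengths")

    def variant_by_length(self, n: int) -> LengthVariant | None:
        for v in self.length_variants:
            if len(v.sites) == n:
                return v
        return None


@dataclass(frozen=True)
class Sublibrary:
    loops: dict[str, LoopDesign]
    weight: float


@dataclass(frozen=True)
class Framework:
    """Conserved reference protein with diversified-region coordinates.

    ``regions`` maps loop id to 0-based half-open residue coordinates of the
    diversified span within the reference protein.
    """

    protein: str
    dna: str
    regions: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.dna) != 3 * len(self.protein):
            raise ValueError("framework DNA length does not match protein length")
        spans = sorted(self.regions.values())
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if c < b:
                raise ValueError("diversified regions overlap")
        for a, b in spans:
            if not (0 <= a < b <= len(self.protein)):
                raise ValueError("diversified region out of bounds")


@dataclass(frozen=True)
class LibraryDesign:
    generation: str
    framework: Framework
    sublibraries: tuple[Sublibrary, ...]
    pooling: str = "independent"  # or "row_matched"

    def __post_init__(self) -> None:
        if not self.sublibraries:
            raise ValueError("design has no sublibraries")
        if self.pooling not in ("independent", "row_matched"):
            raise ValueError(f"unknown pooling mode {self.pooling!r}")
        total = sum(s.weight for s in self.sublibraries)
        if abs(total - 1.0) > _TOL:
            raise ValueError(f"pool weights sum to {total!r}, not 1")
        for sub in self.sublibraries:
            if set(sub.loops) != set(LOOP_IDS):
                raise ValueError("every sublibrary must specify BC, DE and FG loops")

    # -- site lookup helpers -------------------------------------------------

    def loop_of_site(self, site_label: str) -> str:
        for sub in self.sublibraries:
            for loop_id, loop in sub.loops.items():
                for var in loop.length_variants:
                    if site_label in var.labels:
                        return loop_id
        raise KeyError(f"unknown site label {site_label!r}")

    def all_site_labels(self) -> list[str]:
        labels: set[str] = set()
        for sub in self.sublibraries:
            for loop in sub.loops.values():
                for var in loop.length_variants:
                    labels.update(var.labels)
        return sorted(labels, key=site_sort_key)

    def wild_type_residue(self, site_label: str) -> str | None:
        """Reference residue for a site label like ``'D23'``; None for insertions."""
        if site_label[0].isdigit():
            return None
        return site_label[0]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def codon_aa_distribution(mix: NucleotideMix) -> AADistribution:
    """Exact amino-acid/stop distribution of a degenerate codon.

    Enumerates all 64 codons; each codon's probability is the product of its
    three positional nucleotide frequencies.
    """
    probs = {a: 0.0 for a in AA21}
    for n1, n2, n3 in itertools.product(NUCLEOTIDES, repeat=3):
        p = mix.p(0, n1) * mix.p(1, n2) * mix.p(2, n3)
        if p:
            probs[CODON_TABLE[n1 + n2 + n3]] += p
    return AADistribution({a: p for a, p in probs.items() if p > 0.0})


def theoretical_site_distribution(
    design: LibraryDesign, site_label: str, include_stop: bool = True
) -> AADistribution:
    """Pool- and length-weighted mixture distribution at one designed site.

    The mixture runs over every (sublibrary, length variant) that contains the
    site, weighted by pool weight x variant weight, renormalized over the
    containing variants.
    """
    acc = {a: 0.0 for a in AA21}
    total_w = 0.0
    for sub in design.sublibraries:
        for loop in sub.loops.values():
            for var in loop.length_variants:
                for site in var.sites:
                    if site.site_label == site_label:
                        w = sub.weight * var.weight
                        dist = site.distribution()
                        for a, p in dist.probs.items():
                            acc[a] += w * p
                        total_w += w
    if total_w <= 0.0:
        raise KeyError(f"unknown site label {site_label!r}")
    out = AADistribution({a: v / total_w for a, v in acc.items() if v > 0.0})
    return out if include_stop else out.without_stop()


def stop_free_fraction(design: LibraryDesign) -> float:
    """Probability that a sampled clone contains no designed stop codon."""

    def variant_stop_free(var: LengthVariant) -> float:
        p = 1.0
        for site in var.sites:
            if site.kind == "degenerate_codon":
                p *= 1.0 - site.distribution().stop
        return p

    def loop_stop_free(loop: LoopDesign) -> float:
        return sum(v.weight * variant_stop_free(v) for v in loop.length_variants)

    if design.pooling == "row_matched":
        return sum(
            sub.weight * math.prod(loop_stop_free(l) for l in sub.loops.values())
            for sub in design.sublibraries
        )
    # independent per-loop pooling
    out = 1.0
    for loop_id in LOOP_IDS:
        out *= sum(
            sub.weight * loop_stop_free(sub.loops[loop_id])
            for sub in design.sublibraries
        )
    return out


# ---------------------------------------------------------------------------
# Structured design specs (JSON)
# ---------------------------------------------------------------------------

def _parse_site(raw: dict, mixes: dict[str, NucleotideMix]) -> SiteSpec:
    kind = raw["kind"]
    if kind == "degenerate_codon":
        name = raw["mix"]
        if name not in mixes:
            raise ValueError(f"site {raw['label']}: unknown mix {name!r}")
        return SiteSpec(raw["label"], kind, mix=mixes[name], mix_name=name)
    if "aa_probs" in raw:
        probs = {str(a): float(p) for a, p in raw["aa_probs"].items()}
    else:
        aas = raw["aas"]
        if not aas:
            raise ValueError(f"site {raw['label']}: empty amino-acid set")
        probs = {a: 1.0 / len(aas) for a in aas}
    return SiteSpec(raw["label"], kind, aa_probs=probs)


def build_design(spec: dict) -> LibraryDesign:
    """Validate and build a :class:`LibraryDesign` from a structured spec dict.

    See the packaged ``gen1_design.json`` / ``gen2_design.json`` for the
    format.
    """
    mixes = {
        name: NucleotideMix(tuple(
            {nt: float(v) for nt, v in pos.items()} for pos in raw
        ))
        for name, raw in spec.get("mixes", {}).items()
    }
    fw_raw = spec["framework"]
    protein = fw_raw["protein"]
    dna = fw_raw.get("dna") or back_translate(protein)
    framework = Framework(
        protein=protein,
        dna=dna,
        regions={k: tuple(v) for k, v in fw_raw["regions"].items()},
    )
    raw_subs = spec.get("sublibraries", [])
    if not raw_subs:
        raise ValueError("design spec lists no sublibraries")
    default_w = 1.0 / len(raw_subs)
    sublibraries = []
    for raw_sub in raw_subs:
        loops = {}
        for loop_id, raw_loop in raw_sub["loops"].items():
            variants = []
            raw_vars = raw_loop["variants"]
            for raw_var in raw_vars:
                sites = tuple(_parse_site(s, mixes) for s in raw_var["sites"])
                w = float(raw_var.get("weight", 1.0 / len(raw_vars)))
                variants.append(LengthVariant(sites=sites, weight=w))
            loops[loop_id] = LoopDesign(
                loop_id=loop_id,
                anchor_sites=tuple(raw_loop.get("anchors", ("", ""))),
                length_variants=tuple(variants),
            )
        sublibraries.append(
            Sublibrary(loops=loops, weight=float(raw_sub.get("weight", default_w)))
        )
    return LibraryDesign(
        generation=spec.get("generation", "custom"),
        framework=framework,
        sublibraries=tuple(sublibraries),
        pooling=spec.get("pooling", "independent"),
    )


def load_design(name_or_path: str | Path) -> LibraryDesign:
    """Load a packaged design (``'gen1'`` / ``'gen2'``) or a JSON spec file."""
    if str(name_or_path) in ("gen1", "gen2"):
        ref = resources.files("loopscape.data") / f"{name_or_path}_design.json"
        spec = json.loads(ref.read_text())
    else:
        spec = json.loads(Path(name_or_path).read_text())
    return build_design(spec)
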