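"""Clone classification, translation and loop extraction for assembled reads.

Reads are matched against the design's conserved framework using exact 12-nt
anchor sequences flanking each diversified region (configurable to tolerate
one mismatch).  Clones are classified as ``full_length``, ``stop_codon``,
``frameshift`` or ``unidentified``; loops of full-length clones are extracted
and aligned to reference site labels.

Coordinates: reference site labels use the published residue numbers
(``D23`` ... ``K86``); all internal indexing is 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

from .alphabet import CODON_TABLE, STOP, translate
from .library_model import LOOP_IDS, LibraryDesign
from .population_sim import Population, SimulatedClone

ANCHOR_NT = 12

FULL_LENGTH = "full_length"
STOP_CODON = "stop_codon"
FRAMESHIFT = "frameshift"
UNIDENTIFIED = "unidentified"


@dataclass
class CloneRecord:
    id: str
    dna: str
    count: int = 1
    classification: str = UNIDENTIFIED
    protein: str | None = None
    loops: dict[str, str] = field(default_factory=dict)
    site_maps: dict[str, dict[str, str]] = field(default_factory=dict)
    framework_protein: str | None = None


# ---------------------------------------------------------------------------
# Input
# ---------------------------------------------------------------------------

def read_population(path, fmt: str = "fasta") -> Population:
    """Read assembled reads; duplicate sequences aggregate into counts.

    FASTA ids of the form ``...|count=N`` contribute N reads (the simulator's
    FASTA convention); FASTQ records always count 1 each.
    """
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    counts: dict[str, int] = {}
    n_records = 0
    for rec in SeqIO.parse(str(path), fmt):
        n_records += 1
        weight = 1
        for part in rec.description.split("|"):
            if part.startswith("count="):
                weight = int(part.split("=", 1)[1])
        seq = str(rec.seq).upper()
        counts[seq] = counts.get(seq, 0) + weight
    if n_records == 0:
        warnings.warn(f"no records found in {path}")
    clones = [
        SimulatedClone(dna=seq, truth=None, read_count=c)
        for seq, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return Population(clones=clones, label="observed")


# ---------------------------------------------------------------------------
# Anchors and classification
# ---------------------------------------------------------------------------

def _anchors(design: LibraryDesign) -> list[tuple[str, str, str]]:
    """(loop_id, left 12-nt anchor, right 12-nt anchor) per diversified region."""
    fw = design.framework
    out = []
    for loop_id in LOOP_IDS:
        a, b = fw.regions[loop_id]
        left = fw.dna[a * 3 - ANCHOR_NT:a * 3]
        right = fw.dna[b * 3:b * 3 + ANCHOR_NT]
        out.append((loop_id, left, right))
    return out


def _find(haystack: str, needle: str, start: int, max_mismatch: int) -> int:
    pos = haystack.find(needle, start)
    if pos >= 0 or max_mismatch == 0:
        return pos
    n = len(needle)
    for i in range(start, len(haystack) - n + 1):
        mism = 0
        seg = haystack[i:i + n]
        for x, y in zip(seg, needle):
            if x != y:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return i
    return -1


def classify_clone(
    dna: str, design: LibraryDesign, max_mismatch: int = 0
) -> str:
    """Classify a read against the design framework.

    ``frameshift`` when any diversified segment length is not a multiple of 3
    (or anchors fall out of frame); ``stop_codon`` when an in-frame stop occurs
    before the terminus; ``unidentified`` when anchors cannot be located.
    """
    rec = process_read("", dna, 1, design, max_mismatch)
    return rec.classification


def process_read(
    read_id: str,
    dna: str,
    count: int,
    design: LibraryDesign,
    max_mismatch: int = 0,
) -> CloneRecord:
    """Full per-read pipeline: anchor search, frame check, translation,
    loop extraction and site-label alignment."""
    rec = CloneRecord(id=read_id, dna=dna, count=count)
    dna = dna.upper()
    fw = design.framework
    pos = 0
    loop_spans: list[tuple[int, int]] = []  # [start, end) of each loop in read
    for loop_id, left, right in _anchors(design):
        li = _find(dna, left, pos, max_mismatch)
        if li < 0:
            return rec  # unidentified
        ri = _find(dna, right, li + ANCHOR_NT, max_mismatch)
        if ri < 0:
            return rec
        loop_spans.append((li + ANCHOR_NT, ri))
        pos = ri
    if any((b - a) % 3 != 0 for a, b in loop_spans):
        rec.classification = FRAMESHIFT
        return rec

    # Expected framework segment lengths (nt) around the three loops.
    region = [fw.regions[lid] for lid in LOOP_IDS]
    mid_len = [
        (region[1][0] - region[0][1]) * 3,
        (region[2][0] - region[1][1]) * 3,
    ]
    head_len = region[0][0] * 3
    tail_len = (len(fw.protein) - region[2][1]) * 3

    # Inter-loop framework segments must keep reference length, else an indel
    # sits in the framework: frameshift.
    mids = [
        dna[loop_spans[0][1]:loop_spans[1][0]],
        dna[loop_spans[1][1]:loop_spans[2][0]],
    ]
    if [len(m) for m in mids] != mid_len:
        rec.classification = FRAMESHIFT
        return rec

    head = dna[max(loop_spans[0][0] - head_len, 0):loop_spans[0][0]]
    if len(head) < head_len:  # truncated read: pad from the reference
        head = fw.dna[:head_len - len(head)] + head
    tail = dna[loop_spans[2][1]:loop_spans[2][1] + tail_len]
    if len(tail) < tail_len:
        tail = tail + fw.dna[len(fw.dna) - (tail_len - len(tail)):]

    loops_dna = [dna[a:b] for a, b in loop_spans]
    gene = (
        head + loops_dna[0] + mids[0] + loops_dna[1] + mids[1]
        + loops_dna[2] + tail
    )
    if len(gene) % 3 != 0 or any(
        gene[i:i + 3] not in CODON_TABLE for i in range(0, len(gene), 3)
    ):
        rec.classification = FRAMESHIFT
        return rec
    protein = translate(gene)
    rec.protein = protein
    if STOP in protein:
        rec.classification = STOP_CODON
        return rec
    rec.classification = FULL_LENGTH
    for loop_id, seg in zip(LOOP_IDS, loops_dna):
        rec.loops[loop_id] = translate(seg)
    rec.framework_protein = _framework_residues(protein, rec.loops, design)
    for loop_id in LOOP_IDS:
        site_map = align_loop(rec.loops[loop_id], loop_id, design)
        if site_map is not None:
            rec.site_maps[loop_id] = site_map
    return rec


def _framework_residues(
    protein: str, loops: dict[str, str], design: LibraryDesign
) -> str:
    """Concatenated observed framework residues, loop regions excised."""
    fw = design.framework
    out = []
    opos = 0
    fpos = 0
    for loop_id in LOOP_IDS:
        a, _b = fw.regions[loop_id]
        out.append(protein[opos:opos + (a - fpos)])
        opos += (a - fpos) + len(loops[loop_id])
        fpos = fw.regions[loop_id][1]
    out.append(protein[opos:])
    return "".join(out)


def framework_site_labels(design: LibraryDesign) -> list[str]:
    """Reference labels for framework (non-loop) positions, in excised order."""
    fw = design.framework
    labels = []
    fpos = 0
    for loop_id in LOOP_IDS:
        a, b = fw.regions[loop_id]
        labels.extend(
            f"{fw.protein[i]}{i + 1}" for i in range(fpos, a)
        )
        fpos = b
    labels.extend(f"{fw.protein[i]}{i + 1}" for i in range(fpos, len(fw.protein)))
    return labels


def extract_loops(rec: CloneRecord, design: LibraryDesign) -> dict[str, str]:
    """Loop residues strictly between framework anchors (full-length only)."""
    if rec.classification != FULL_LENGTH:
        raise ValueError("loops are only defined for full-length clones")
    return dict(rec.loops)


# ---------------------------------------------------------------------------
# Loop alignment to reference site labels
# ---------------------------------------------------------------------------

def align_loop(
    loop_residues: str, loop_id: str, design: LibraryDesign
) -> dict[str, str] | None:
    """Map loop residues to reference site labels by length-variant lookup.

    Returns None (unaligned) when no design length variant matches the
    observed loop length.
    """
    n = len(loop_residues)
    for sub in design.sublibraries:
        for v in sub.loops[loop_id].length_variants:
            if len(v.sites) == n:
                return {
                    site.site_label: aa
                    for site, aa in zip(v.sites, loop_residues)
                }
    return None


def process_population(
    pop: Population, design: LibraryDesign, max_mismatch: int = 0
) -> list[CloneRecord]:
    return [
        process_read(f"clone_{i}", c.dna, c.read_count, design, max_mismatch)
        for i, c in enumerate(pop.clones)
    ]


def write_clone_table(records: list[CloneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tcount\tclassification\tBC\tDE\tFG\n")
        for r in records:
            fh.write(
                f"{r.id}\t{r.count}\t{r.classification}\t"
                f"{r.loops.get('BC', '')}\t{r.loops.get('DE', '')}\t"
                f"{r.loops.get('FG', '')}\n"
            )
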