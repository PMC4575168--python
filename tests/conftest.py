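import numpy as np
import pytest

from loopscape.library_model import build_design, load_design

# A small framework (30 aa) with three diversified regions, used to build
# cheap toy designs: BC = residues 9-10, DE = 15-16, FG = 21-22 (1-based).
TOY_FRAMEWORK = "MKTAYIAKQRQISFVKSHFSRQLEERLGLI"
TOY_REGIONS = {"BC": [8, 10], "DE": [14, 16], "FG": [20, 22]}


def toy_site(label, aas=None, mix=None):
    if mix is not None:
        return {"label": label, "kind": "degenerate_codon", "mix": mix}
    if isinstance(aas, dict):
        return {"label": label, "kind": "fixed_set", "aa_probs": aas}
    kind = "conserved" if len(aas) == 1 else "fixed_set"
    return {"label": label, "kind": kind, "aas": list(aas)}


def toy_design_spec(bc_variants=None, de_variants=None, fg_variants=None,
                    mixes=None, pooling="independent", weights=None):
    """Single-sublibrary toy design; default loops are conserved 2-mers."""
    def default(labels):
        return [{"weight": 1.0,
                 "sites": [toy_site(lab, lab[0]) for lab in labels]}]

    # labels match the toy framework residues at the diversified regions
    bc = bc_variants or default(["Q9", "R10"])
    de = de_variants or default(["V15", "K16"])
    fg = fg_variants or default(["R21", "Q22"])
    return {
        "generation": "toy",
        "pooling": pooling,
        "mixes": mixes or {},
        "framework": {"protein": TOY_FRAMEWORK, "regions": TOY_REGIONS},
        "sublibraries": [
            {"weight": 1.0, "loops": {
                "BC": {"variants": bc},
                "DE": {"variants": de},
                "FG": {"variants": fg},
            }}
        ],
    }


CDR_MIX = [
    {"A": 0.20, "C": 0.15, "G": 0.25, "T": 0.40},
    {"A": 0.50, "C": 0.25, "G": 0.15, "T": 0.10},
    {"A": 0.00, "C": 0.45, "G": 0.10, "T": 0.45},
]


@pytest.fixture(scope="session")
def gen1():
    return load_design("gen1")


@pytest.fixture(scope="session")
def gen2():
    return load_design("gen2")


@pytest.fixture
def toy_design():
    return build_design(toy_design_spec())


@pytest.fixture
def sy_design():
    """Toy design whose BC loop has two equal S/Y sites (DE/FG conserved)."""
    bc = [{"weight": 1.0, "sites": [toy_site("Q9", "SY"), toy_site("R10", "SY")]}]
    return build_design(toy_design_spec(bc_variants=bc))


@pytest.fixture(scope="session")
def gen1_pop_small(gen1):
    from loopscape.population_sim import sample_population

    return sample_population(gen1, 2000, seed=101)


@pytest.fixture(scope="session")
def gen1_records_small(gen1, gen1_pop_small):
    from loopscape.seq_processing import process_population

    return process_population(gen1_pop_small, gen1)


# ---------------------------------------------------------------------------
# PDB fixture helper
# ---------------------------------------------------------------------------

def write_pdb(path, atoms, models=1):
    """Write a minimal PDB file.

    ``atoms``: list of (atom_name, res_name, res_id, x, y, z, element).
    """
    lines = []
    for m in range(1, models + 1):
        if models > 1:
            lines.append(f"MODEL     {m:4d}")
        for i, (name, res, rid, x, y, z, el) in enumerate(atoms, start=1):
            lines.append(
                f"ATOM  {i:5d} {name:<4s} {res:>3s} A{rid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el:>2s}"
            )
        if models > 1:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
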