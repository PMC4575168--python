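"""Per-site exposure scores from structure: SASA x orientation accessibility.

Implements Shrake-Rupley solvent-accessible surface area on a quasi-uniform
(Fibonacci) sphere sampling, relative SASA against extended-state reference
areas, alanine truncation of diversified loops, and the orientation-search
accessibility algorithm: viewing directions are scanned coarse-then-fine, the
projected visible area of the diversified side-chain spheres is computed by
orthographic z-buffer rasterization, and each site's accessibility is its
maximal visible area over all orientations within 5% of the best total view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_RADIUS = 1.70
PROBE_RADIUS = 1.40

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "CB"}


@dataclass
class StructureModel:
    """Minimal atom-level structure: coordinates, elements, residue ids."""

    coords: np.ndarray           # (n, 3) Angstroms
    elements: np.ndarray         # (n,) str
    atom_names: np.ndarray       # (n,) str, e.g. 'CA', 'CB'
    res_ids: np.ndarray          # (n,) int residue numbers
    res_names: np.ndarray        # (n,) str 3-letter residue names
    chains: np.ndarray           # (n,) str
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.coords) == 0:
            raise ValueError("structure has no atoms")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def radii(self) -> np.ndarray:
        out = np.empty(len(self), dtype=float)
        for i, el in enumerate(self.elements):
            r = VDW_RADII.get(el)
            if r is None:
                warnings.warn(f"unknown element {el!r}: using default radius")
                r = DEFAULT_RADIUS
            out[i] = r
        return out


def parse_structure(path) -> StructureModel:
    """Read the first model of a PDB file into a :class:`StructureModel`."""
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    if pdb_file.get_model_count() == 0:
        raise ValueError(f"no ATOM records in {path}")
    atoms = pdb_file.get_structure(model=1)
    atoms = atoms[atoms.element != "H"]
    if atoms.array_length() == 0:
        raise ValueError(f"no heavy atoms in {path}")
    return StructureModel(
        coords=np.asarray(atoms.coord, dtype=float),
        elements=np.asarray(atoms.element, dtype=str),
        atom_names=np.asarray(atoms.atom_name, dtype=str),
        res_ids=np.asarray(atoms.res_id, dtype=int),
        res_names=np.asarray(atoms.res_name, dtype=str),
        chains=np.asarray(atoms.chain_id, dtype=str),
        source=str(path),
    )


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit sphere points (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(
    structure: StructureModel,
    probe: float = PROBE_RADIUS,
    n_points: int = 960,
) -> tuple[np.ndarray, pd.Series]:
    """Per-atom and per-residue solvent-accessible surface areas (A^2)."""
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    coords = structure.coords
    radii = structure.radii + probe
    sphere = _fibonacci_sphere(n_points)
    n = len(coords)
    areas = np.zeros(n)
    # neighbor prefilter via max expanded radius
    max_r = radii.max()
    for i in range(n):
        d = np.linalg.norm(coords - coords[i], axis=1)
        near = np.flatnonzero((d < radii[i] + max_r) & (np.arange(n) != i))
        pts = coords[i] + radii[i] * sphere
        if near.size:
            d2 = ((pts[:, None, :] - coords[near][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (radii[near] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * radii[i] ** 2
    agg: dict[tuple[str, int], float] = {}
    for c, r, a in zip(structure.chains, structure.res_ids, areas):
        key = (str(c), int(r))
        agg[key] = agg.get(key, 0.0) + a
    return areas, pd.Series(agg)


# Theoretical maximum accessible areas in extended Gly-X-Gly tripeptides
# (Tien et al. 2013), A^2.
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

EXPOSED_THRESHOLD = 0.40


def relative_sasa(area: float, res_name: str) -> float:
    """Residue area divided by its extended-state reference maximum."""
    try:
        return area / MAX_SASA[res_name.upper()]
    except KeyError:
        raise ValueError(f"unknown residue type {res_name!r}") from None


def is_exposed(rel_sasa: float, threshold: float = EXPOSED_THRESHOLD) -> bool:
    """Exposure classification; the boundary value counts as exposed."""
    return rel_sasa >= threshold


def residue_relative_sasa(
    structure: StructureModel, probe: float = PROBE_RADIUS, n_points: int = 960
) -> pd.Series:
    _, per_res = sasa(structure, probe=probe, n_points=n_points)
    name_of = {}
    for c, r, nm in zip(structure.chains, structure.res_ids, structure.res_names):
        name_of[(c, int(r))] = nm
    return pd.Series(
        {k: relative_sasa(v, name_of[k]) for k, v in per_res.items()}
    )


# ---------------------------------------------------------------------------
# Alanine truncation and orientation accessibility
# ---------------------------------------------------------------------------

def ala_truncate(structure: StructureModel, sites: list[int]) -> StructureModel:
    """Remove side-chain atoms beyond C-beta at the listed residue numbers."""
    site_set = set(sites)
    keep = np.array(
        [
            (int(r) not in site_set) or (name in BACKBONE_ATOMS)
            for r, name in zip(structure.res_ids, structure.atom_names)
        ]
    )
    return StructureModel(
        coords=structure.coords[keep],
        elements=structure.elements[keep],
        atom_names=structure.atom_names[keep],
        res_ids=structure.res_ids[keep],
        res_names=structure.res_names[keep],
        chains=structure.chains[keep],
        source=structure.source,
    )


def _view_rotation(theta: float, phi: float) -> np.ndarray:
    """Rotation matrix bringing the (theta, phi) direction onto +z."""
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    # rotate by -phi about z, then -theta about y
    rz = np.array([[cp, sp, 0.0], [-sp, cp, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[ct, 0.0, -st], [0.0, 1.0, 0.0], [st, 0.0, ct]])
    return ry @ rz


def _visible_areas(
    coords: np.ndarray,
    radii: np.ndarray,
    site_atom_idx: np.ndarray,
    rot: np.ndarray,
    grid: float,
) -> np.ndarray:
    """Visible projected area per tracked sphere under one orientation."""
    xyz = coords @ rot.T
    lo = (xyz[:, :2] - radii[:, None]).min(axis=0) - grid
    hi = (xyz[:, :2] + radii[:, None]).max(axis=0) + grid
    nx = int(np.ceil((hi[0] - lo[0]) / grid))
    ny = int(np.ceil((hi[1] - lo[1]) / grid))
    zbuf = np.full((nx, ny), -np.inf)
    owner = np.full((nx, ny), -1, dtype=np.int64)
    for k in range(len(coords)):
        r = radii[k]
        cx, cy, cz = xyz[k]
        x0 = max(int((cx - r - lo[0]) / grid), 0)
        x1 = min(int((cx + r - lo[0]) / grid) + 2, nx)
        y0 = max(int((cy - r - lo[1]) / grid), 0)
        y1 = min(int((cy + r - lo[1]) / grid) + 2, ny)
        if x0 >= x1 or y0 >= y1:
            continue
        gx = lo[0] + (np.arange(x0, x1) + 0.5) * grid
        gy = lo[1] + (np.arange(y0, y1) + 0.5) * grid
        dx2 = (gx - cx)[:, None] ** 2
        dy2 = (gy - cy)[None, :] ** 2
        inside = dx2 + dy2 <= r * r
        zfront = np.where(inside, cz + np.sqrt(np.maximum(r * r - dx2 - dy2, 0.0)), -np.inf)
        patch_z = zbuf[x0:x1, y0:y1]
        patch_o = owner[x0:x1, y0:y1]
        wins = zfront > patch_z
        patch_z[wins] = zfront[wins]
        patch_o[wins] = k
    cell = grid * grid
    return np.array(
        [(owner == k).sum() * cell for k in site_atom_idx]
    )


def orientation_accessibility(
    structure: StructureModel,
    sites: list[int],
    coarse_step: float = 10.0,
    fine_step: float = 1.0,
    tol: float = 0.05,
    grid: float = 0.25,
) -> pd.Series:
    """Max visible side-chain projected area per diversified site.

    Diversified side chains are represented by their C-beta sphere (the
    structure should be alanine-truncated first).  A coarse orientation grid
    finds the view maximizing the total visible diversified area; a fine grid
    refines around it; every orientation within ``tol`` of the best total
    area contributes, and each site reports its maximum own visible area over
    that orientation set.
    """
    site_set = set(sites)
    site_atom_idx = np.array(
        [
            i
            for i in range(len(structure))
            if int(structure.res_ids[i]) in site_set
            and structure.atom_names[i] == "CB"
        ]
    )
    if site_atom_idx.size == 0:
        raise ValueError("no diversified C-beta atoms found")
    coords = structure.coords
    radii = structure.radii

    def evaluate(angles):
        results = []
        for theta, phi in angles:
            vis = _visible_areas(
                coords, radii, site_atom_idx, _view_rotation(theta, phi), grid
            )
            results.append(((theta, phi), vis))
        return results

    coarse = [
        (np.radians(t), np.radians(p))
        for t in np.arange(0.0, 180.0 + 1e-9, coarse_step)
        for p in np.arange(0.0, 360.0, coarse_step)
        if not (t in (0.0, 180.0) and p > 0.0)
    ]
    evaluated = evaluate(coarse)
    best_angles, _ = max(evaluated, key=lambda r: r[1].sum())
    t0, p0 = np.degrees(best_angles)
    fine = [
        (np.radians(t), np.radians(p % 360.0))
        for t in np.arange(t0 - coarse_step, t0 + coarse_step + 1e-9, fine_step)
        for p in np.arange(p0 - coarse_step, p0 + coarse_step + 1e-9, fine_step)
        if 0.0 <= t <= 180.0
    ]
    evaluated += evaluate(fine)
    best_total = max(r[1].sum() for r in evaluated)
    within = [vis for _, vis in evaluated if vis.sum() >= (1.0 - tol) * best_total]
    per_site_best = np.max(np.stack(within), axis=0)
    res_of_atom = [int(structure.res_ids[i]) for i in site_atom_idx]
    return pd.Series(per_site_best, index=res_of_atom)


def exposure_score(
    structures: list[StructureModel],
    sites: list[int],
    sasa_points: int = 960,
    **orient_kwargs,
) -> pd.DataFrame:
    """Combine relative SASA and orientation accessibility into epsilon.

    Per site: (mean relative SASA over structures) x (mean normalized
    accessibility over structures); the product is rescaled to [0, 1] by its
    maximum across sites.  Sites missing from every structure raise.
    """
    if not structures:
        raise ValueError("need at least one structure")
    rel_acc: dict[int, list[float]] = {s: [] for s in sites}
    rel_sasa: dict[int, list[float]] = {s: [] for s in sites}
    for structure in structures:
        rs = residue_relative_sasa(structure, n_points=sasa_points)
        trunc = ala_truncate(structure, sites)
        acc = orientation_accessibility(trunc, sites, **orient_kwargs)
        amax = acc.max()
        for s in sites:
            present = [
                k for k in rs.index if k[1] == s
            ]
            if present:
                rel_sasa[s].append(float(rs[present[0]]))
            if s in acc.index:
                rel_acc[s].append(float(acc[s] / amax) if amax > 0 else 0.0)
    rows = []
    for s in sites:
        if not rel_sasa[s] and not rel_acc[s]:
            raise ValueError(f"site {s} absent in all structures")
        mean_sasa = float(np.mean(rel_sasa[s])) if rel_sasa[s] else 0.0
        mean_acc = float(np.mean(rel_acc[s])) if rel_acc[s] else 0.0
        rows.append(
            {
                "site": s,
                "relative_sasa": mean_sasa,
                "accessibility": mean_acc,
                "raw": mean_sasa * mean_acc,
            }
        )
    df = pd.DataFrame(rows).set_index("site")
    peak = df["raw"].max()
    df["epsilon"] = df["raw"] / peak if peak > 0 else 0.0
    return df
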