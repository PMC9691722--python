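"""TCR-pMHC docking-geometry descriptors, contacts, SASA and CDR3 statistics.

Descriptors follow the conventions of the TCR structural literature:

* crossing angle -- angle between the line joining the Valpha and Vbeta
  intradomain disulfide centroids and a line fit to the peptide C-alpha
  atoms (oriented N->C), both projected onto the least-squares plane of the
  MHC peptide-binding groove; reported in [0, 180] degrees.
* COM angle -- same construction with the disulfide line replaced by the
  line joining the Valpha and Vbeta variable-domain geometric centers.
* polar coordinates (theta, phi, r) -- azimuth, tilt and distance of the
  combined variable-domain center relative to the groove center, in a frame
  whose z axis is the groove-plane normal (oriented toward the TCR) and
  whose x axis is the in-plane projection of the peptide N->C axis.

Centers of mass are geometric centers of non-hydrogen atoms (unit masses);
element mass weighting moves the descriptors by well under the reporting
tolerance.  Residue numbering is taken from the file as-is (author
numbering, 1-based, inclusive ranges).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import norm as _norm

from .errors import InvalidParameterError, StructureError

__all__ = [
    "ChainAnnotation",
    "StructureComplex",
    "DockingGeometry",
    "ContactTable",
    "CdrLengthStats",
    "load_structure",
    "crossing_angle",
    "com_angle",
    "polar_coordinates",
    "docking_geometry",
    "contacts",
    "sasa",
    "cdr3_extract",
    "loop_length_stats",
    "normal_tail_percent",
    "VDW_RADII",
]

# Bondi-style van der Waals radii (Angstrom) by element symbol.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "FE": 2.00, "ZN": 1.39, "MG": 1.73, "CA": 2.31, "NA": 2.27, "K": 2.75,
}


@dataclass
class ChainAnnotation:
    """Which chain is which, plus the residue ranges the descriptors need.

    Ranges are author-numbered, 1-based, inclusive (start, end) tuples.
    ``v_domain_ranges`` maps the TCR alpha/beta chain ids to their variable
    domains; ``groove_range`` selects the MHC peptide-binding platform on
    the heavy chain (class I default: residues 1-180, alpha1+alpha2).
    """

    tcr_alpha: str
    tcr_beta: str
    mhc_heavy: str
    peptide: str
    beta2m: str | None = None
    v_domain_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    groove_range: tuple[int, int] = (1, 180)
    alpha2_helix_range: tuple[int, int] = (138, 180)


@dataclass
class StructureComplex:
    """Flat atom table of one model plus its chain annotation."""

    coords: np.ndarray  # (n, 3) Angstrom
    elements: np.ndarray  # (n,) element symbols, upper case
    atom_names: np.ndarray  # (n,)
    res_numbers: np.ndarray  # (n,) ints (author numbering)
    res_names: np.ndarray  # (n,)
    chain_ids: np.ndarray  # (n,)
    annotation: ChainAnnotation

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.coords.shape[0]
        for name in ("elements", "atom_names", "res_names", "chain_ids"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
            if getattr(self, name).shape[0] != n:
                raise StructureError(f"{name} length mismatch")
        self.res_numbers = np.asarray(self.res_numbers, dtype=int)
        ann = self.annotation
        present = set(self.chain_ids)
        for label in ("tcr_alpha", "tcr_beta", "mhc_heavy", "peptide"):
            cid = getattr(ann, label)
            if cid not in present:
                raise StructureError(
                    f"annotated {label} chain {cid!r} not found in structure "
                    f"(chains present: {sorted(present)})"
                )

    def __len__(self) -> int:
        return self.coords.shape[0]

    # ---- selections ----------------------------------------------------
    def mask(
        self,
        chain: str | None = None,
        res_range: tuple[int, int] | None = None,
        atom_name: str | None = None,
    ) -> np.ndarray:
        m = np.ones(len(self), dtype=bool)
        if chain is not None:
            m &= self.chain_ids == chain
        if res_range is not None:
            m &= (self.res_numbers >= res_range[0]) & (
                self.res_numbers <= res_range[1]
            )
        if atom_name is not None:
            m &= self.atom_names == atom_name
        return m

    def v_domain_mask(self, chain: str) -> np.ndarray:
        rng = self.annotation.v_domain_ranges.get(chain)
        if rng is None:
            raise StructureError(f"no variable-domain range annotated for chain {chain!r}")
        return self.mask(chain=chain, res_range=rng)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureComplex":
        """Rigid-body copy: x -> R x + t."""
        return StructureComplex(
            coords=self.coords @ np.asarray(rotation, dtype=float).T
            + np.asarray(translation, dtype=float),
            elements=self.elements.copy(),
            atom_names=self.atom_names.copy(),
            res_numbers=self.res_numbers.copy(),
            res_names=self.res_names.copy(),
            chain_ids=self.chain_ids.copy(),
            annotation=self.annotation,
        )


@dataclass(frozen=True)
class DockingGeometry:
    crossing_angle: float  # degrees, [0, 180]
    com_angle: float  # degrees, [0, 180]
    theta: float  # degrees, (-180, 180]: groove-plane azimuth (rotation)
    phi: float  # degrees, [0, 180]: tilt from the groove normal
    r: float  # Angstrom, COM-COM distance
    canonical_polarity: bool | None = None


@dataclass(frozen=True)
class ContactTable:
    cutoff: float
    pairs: pd.DataFrame  # chain_a,res_a,resname_a,chain_b,res_b,resname_b,n_atom_pairs

    @property
    def n_residue_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_atom_pairs(self) -> int:
        return int(self.pairs["n_atom_pairs"].sum()) if len(self.pairs) else 0


@dataclass(frozen=True)
class CdrLengthStats:
    lengths: tuple[int, ...]
    mean: float
    sd: float
    query_length: int
    z_score: float
    normal_tail_percent: float
    empirical_tail_percent: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# structure loading (gemmi)
# ---------------------------------------------------------------------------


def load_structure(path, annotation: ChainAnnotation) -> StructureComplex:
    """Read a PDB or mmCIF file into a StructureComplex.

    Keeps the first model only, drops hydrogens and waters, and retains
    blank or 'A' altlocs.
    """
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises bare RuntimeError/ValueError
        raise StructureError(f"cannot read structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    model = st[0]

    coords, elements, atom_names, res_numbers, res_names, chain_ids = (
        [], [], [], [], [], [],
    )
    for chain in model:
        for res in chain:
            if res.name in ("HOH", "WAT", "DOD"):
                continue
            for atom in res:
                if atom.altloc not in ("", "A", "\0"):
                    continue
                elem = atom.element.name.upper()
                if elem == "H" or elem == "D":
                    continue
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                elements.append(elem)
                atom_names.append(atom.name)
                res_numbers.append(res.seqid.num)
                res_names.append(res.name)
                chain_ids.append(chain.name)
    if not coords:
        raise StructureError(f"no usable atoms in {path}")
    return StructureComplex(
        coords=np.asarray(coords, dtype=float),
        elements=np.asarray(elements, dtype=object),
        atom_names=np.asarray(atom_names, dtype=object),
        res_numbers=np.asarray(res_numbers, dtype=int),
        res_names=np.asarray(res_names, dtype=object),
        chain_ids=np.asarray(chain_ids, dtype=object),
        annotation=annotation,
    )


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise InvalidParameterError("zero-length vector")
    return v / n


def _plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through points (SVD)."""
    if points.shape[0] < 3:
        raise StructureError("need >= 3 points to fit a plane")
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[-1] > 0 and s[-2] / max(s[-1], 1e-30) < 1.0 + 1e-9:
        pass  # nearly isotropic: normal still defined, just poorly
    return vt[-1]


def _principal_axis(points: np.ndarray, orient: np.ndarray) -> np.ndarray:
    """First principal axis of points, oriented along ``orient``."""
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 1e-9:
        raise StructureError("degenerate (collinear/coincident) point set")
    axis = vt[0]
    if axis @ orient < 0:
        axis = -axis
    return axis


def _project_on_plane(v: np.ndarray, normal: np.ndarray) -> np.ndarray:
    return v - (v @ normal) * normal


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.clip(_unit(u) @ _unit(v), -1.0, 1.0))
    return math.degrees(math.acos(c))


def _peptide_ca(cx: StructureComplex) -> np.ndarray:
    m = cx.mask(chain=cx.annotation.peptide, atom_name="CA")
    pts = cx.coords[m]
    order = np.argsort(cx.res_numbers[m], kind="stable")
    pts = pts[order]
    if pts.shape[0] < 3:
        raise StructureError("peptide chain has fewer than 3 C-alpha atoms")
    return pts


def _groove_ca(cx: StructureComplex) -> np.ndarray:
    ann = cx.annotation
    m = cx.mask(chain=ann.mhc_heavy, res_range=ann.groove_range, atom_name="CA")
    pts = cx.coords[m]
    if pts.shape[0] < 3:
        raise StructureError(
            f"groove range {ann.groove_range} on chain {ann.mhc_heavy!r} has "
            f"fewer than 3 C-alpha atoms"
        )
    return pts


def _disulfide_centroid(cx: StructureComplex, chain: str) -> np.ndarray:
    """Centroid of the intradomain disulfide of a V domain.

    Uses the closest pair of CYS S-gamma atoms inside the annotated
    variable-domain range (bond distance <= 3.0 A); falls back to the
    closest CYS C-alpha pair when S-gamma atoms are absent.
    """
    vmask = cx.v_domain_mask(chain)
    cys = vmask & (cx.res_names == "CYS")
    for atom in ("SG", "CA"):
        m = cys & (cx.atom_names == atom)
        pts = cx.coords[m]
        if pts.shape[0] >= 2:
            d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            i, j = np.unravel_index(np.argmin(d), d.shape)
            max_bond = 3.0 if atom == "SG" else 8.0
            if d[i, j] <= max_bond:
                return (pts[i] + pts[j]) / 2.0
    raise StructureError(
        f"no intradomain disulfide found in the V domain of chain {chain!r}"
    )


def _v_com(cx: StructureComplex, chain: str) -> np.ndarray:
    return cx.coords[cx.v_domain_mask(chain)].mean(axis=0)


def _groove_frame(cx: StructureComplex):
    """Return (origin, x, y, z) of the groove frame.

    z: groove-plane normal oriented toward the TCR variable domains;
    x: in-plane projection of the peptide N->C principal axis; y = z cross x.
    """
    ann = cx.annotation
    groove_pts = _groove_ca(cx)
    origin = groove_pts.mean(axis=0)
    normal = _plane_normal(groove_pts)

    va = _v_com(cx, ann.tcr_alpha)
    vb = _v_com(cx, ann.tcr_beta)
    tcr_com = (cx.coords[cx.v_domain_mask(ann.tcr_alpha)].sum(axis=0)
               + cx.coords[cx.v_domain_mask(ann.tcr_beta)].sum(axis=0))
    n_atoms = cx.v_domain_mask(ann.tcr_alpha).sum() + cx.v_domain_mask(ann.tcr_beta).sum()
    tcr_com = tcr_com / n_atoms
    if (tcr_com - origin) @ normal < 0:
        normal = -normal

    pep = _peptide_ca(cx)
    axis = _principal_axis(pep, orient=pep[-1] - pep[0])
    x = _project_on_plane(axis, normal)
    if np.linalg.norm(x) < 1e-9:
        raise StructureError("peptide axis is perpendicular to the groove plane")
    x = _unit(x)
    z = normal
    y = np.cross(z, x)
    return origin, x, y, z, tcr_com, va, vb


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------


def crossing_angle(cx: StructureComplex) -> float:
    """Docking crossing angle in degrees, [0, 180]."""
    ann = cx.annotation
    _, x, _, z, _, _, _ = _groove_frame(cx)
    sa = _disulfide_centroid(cx, ann.tcr_alpha)
    sb = _disulfide_centroid(cx, ann.tcr_beta)
    line = _project_on_plane(sb - sa, z)
    if np.linalg.norm(line) < 1e-9:
        raise StructureError("disulfide axis is perpendicular to the groove plane")
    return _angle_deg(line, x)


def com_angle(cx: StructureComplex) -> float:
    """Variable-domain center-of-mass angle in degrees, [0, 180]."""
    ann = cx.annotation
    _, x, _, z, _, va, vb = _groove_frame(cx)
    line = _project_on_plane(vb - va, z)
    if np.linalg.norm(line) < 1e-9:
        raise StructureError("COM axis is perpendicular to the groove plane")
    return _angle_deg(line, x)


def polar_coordinates(cx: StructureComplex) -> tuple[float, float, float]:
    """(theta, phi, r): azimuth deg, tilt deg, distance Angstrom."""
    origin, x, y, z, tcr_com, _, _ = _groove_frame(cx)
    d = tcr_com - origin
    r = float(np.linalg.norm(d))
    if r <= 0:
        raise StructureError("TCR and groove centers coincide")
    phi = _angle_deg(d, z)
    in_plane = _project_on_plane(d, z)
    if np.linalg.norm(in_plane) < 1e-9:
        theta = 0.0  # directly above the groove COM: azimuth undefined
    else:
        theta = math.degrees(math.atan2(in_plane @ y, in_plane @ x))
    return theta, phi, r


def docking_geometry(cx: StructureComplex) -> DockingGeometry:
    """All docking descriptors plus a Valpha-over-alpha2 polarity check."""
    theta, phi, r = polar_coordinates(cx)
    ann = cx.annotation
    polarity: bool | None = None
    a2 = cx.mask(chain=ann.mhc_heavy, res_range=ann.alpha2_helix_range, atom_name="CA")
    if a2.sum() >= 3:
        a2_com = cx.coords[a2].mean(axis=0)
        va = _v_com(cx, ann.tcr_alpha)
        vb = _v_com(cx, ann.tcr_beta)
        polarity = bool(
            np.linalg.norm(va - a2_com) < np.linalg.norm(vb - a2_com)
        )
    return DockingGeometry(
        crossing_angle=crossing_angle(cx),
        com_angle=com_angle(cx),
        theta=theta,
        phi=phi,
        r=r,
        canonical_polarity=polarity,
    )


# ---------------------------------------------------------------------------
# contacts and SASA
# ---------------------------------------------------------------------------


def contacts(
    cx: StructureComplex,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff: float = 4.0,
) -> ContactTable:
    """Residue-pair contact table across two atom groups (boolean masks).

    Counts non-hydrogen atom pairs within ``cutoff`` Angstrom, aggregated
    per residue pair.  Groups must be disjoint.
    """
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    if np.any(group_a & group_b):
        raise InvalidParameterError("contact groups overlap")
    if cutoff <= 0:
        raise InvalidParameterError("cutoff must be > 0")
    ia = np.flatnonzero(group_a)
    ib = np.flatnonzero(group_b)
    if ia.size == 0 or ib.size == 0:
        raise InvalidParameterError("contact groups must be non-empty")

    tree_b = cKDTree(cx.coords[ib])
    neighbors = tree_b.query_ball_point(cx.coords[ia], r=cutoff)
    records: dict[tuple, int] = {}
    for k, nbrs in enumerate(neighbors):
        if not nbrs:
            continue
        i = ia[k]
        key_a = (cx.chain_ids[i], int(cx.res_numbers[i]), cx.res_names[i])
        for nb in nbrs:
            j = ib[nb]
            key = key_a + (cx.chain_ids[j], int(cx.res_numbers[j]), cx.res_names[j])
            records[key] = records.get(key, 0) + 1
    df = pd.DataFrame(
        [k + (v,) for k, v in sorted(records.items())],
        columns=[
            "chain_a", "res_a", "resname_a",
            "chain_b", "res_b", "resname_b", "n_atom_pairs",
        ],
    )
    return ContactTable(cutoff=cutoff, pairs=df)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(
    cx: StructureComplex,
    probe: float = 1.4,
    n_points: int = 960,
    subset: np.ndarray | None = None,
) -> pd.DataFrame:
    """Shrake-Rupley solvent-accessible surface area per residue.

    Each atom is inflated by the probe radius and sampled with a fixed
    golden-spiral point set; points buried inside any neighboring inflated
    atom are occluded.  Deterministic for a given ``n_points``.

    Returns a DataFrame (chain, res_number, res_name, area_A2).
    """
    if probe < 0:
        raise InvalidParameterError("probe radius must be >= 0")
    mask = np.ones(len(cx), dtype=bool) if subset is None else np.asarray(subset, bool)
    idx = np.flatnonzero(mask)
    unknown = [e for e in set(cx.elements[idx]) if e not in VDW_RADII]
    if unknown:
        bad = idx[np.isin(cx.elements[idx], unknown)][0]
        raise StructureError(
            f"no van der Waals radius for element {cx.elements[bad]!r} "
            f"(atom {cx.atom_names[bad]} in {cx.res_names[bad]} "
            f"{cx.res_numbers[bad]}, chain {cx.chain_ids[bad]})"
        )
    radii = np.array([VDW_RADII[e] for e in cx.elements[idx]]) + probe
    coords = cx.coords[idx]
    unit = _sphere_points(n_points)

    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.zeros(idx.size)
    for k in range(idx.size):
        pts = coords[k] + radii[k] * unit
        nbrs = [j for j in tree.query_ball_point(coords[k], r=radii[k] + max_r)
                if j != k]
        exposed = np.ones(n_points, dtype=bool)
        for j in nbrs:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > radii[j] ** 2
            if not exposed.any():
                break
        areas[k] = 4.0 * math.pi * radii[k] ** 2 * exposed.sum() / n_points

    df = pd.DataFrame(
        {
            "chain": cx.chain_ids[idx],
            "res_number": cx.res_numbers[idx],
            "res_name": cx.res_names[idx],
            "area_A2": areas,
        }
    )
    return (
        df.groupby(["chain", "res_number", "res_name"], as_index=False, sort=True)[
            "area_A2"
        ]
        .sum()
    )


# ---------------------------------------------------------------------------
# CDR3 loops
# ---------------------------------------------------------------------------

_J_MOTIF = re.compile(r"[FW]G.G")


def cdr3_extract(
    chain_sequence: str,
    boundaries: tuple[int, int] | None = None,
) -> tuple[str, int]:
    """CDR3 loop of a TCR chain sequence, inclusive of both boundary residues.

    The loop runs from the conserved second framework cysteine through the
    J-region Phe/Trp of the [FW]G.G motif.  ``boundaries`` (0-based,
    inclusive start and end indices) overrides the motif rule.

    Returns (loop_sequence, length).
    """
    seq = chain_sequence.upper()
    if boundaries is not None:
        lo, hi = boundaries
        if not (0 <= lo <= hi < len(seq)):
            raise InvalidParameterError(f"boundaries {boundaries} out of range")
        loop = seq[lo : hi + 1]
        return loop, len(loop)

    m = _J_MOTIF.search(seq)
    if m is None:
        raise InvalidParameterError(
            "no [FW]G.G J-region motif found; supply explicit boundaries"
        )
    end = m.start()  # index of the F/W, included in the loop
    cys_positions = [i for i, c in enumerate(seq[:end]) if c == "C"]
    if len(cys_positions) < 2:
        raise InvalidParameterError(
            "fewer than two cysteines before the J motif; supply explicit boundaries"
        )
    start = cys_positions[1]
    loop = seq[start : end + 1]
    return loop, len(loop)


def loop_length_stats(lengths, query_length: int) -> CdrLengthStats:
    """Mean/SD, z-score and tail probabilities of a loop-length sample.

    The normal tail is the upper-tail percent P(X >= query) of a normal
    distribution with the sample mean and SD; the empirical tail is the
    observed fraction of lengths >= query.
    """
    arr = np.asarray(list(lengths), dtype=float)
    if arr.size < 2:
        raise InvalidParameterError("need >= 2 lengths")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    empirical = float((arr >= query_length).mean() * 100.0)
    if sd == 0:
        return CdrLengthStats(
            lengths=tuple(int(v) for v in arr),
            mean=mean, sd=0.0, query_length=query_length,
            z_score=math.inf if query_length > mean else -math.inf,
            normal_tail_percent=0.0 if query_length > mean else 100.0,
            empirical_tail_percent=empirical,
            degenerate=True,
        )
    z = (query_length - mean) / sd
    return CdrLengthStats(
        lengths=tuple(int(v) for v in arr),
        mean=mean,
        sd=sd,
        query_length=query_length,
        z_score=float(z),
        normal_tail_percent=normal_tail_percent(mean, sd, query_length),
        empirical_tail_percent=empirical,
        degenerate=False,
    )


def normal_tail_percent(mean: float, sd: float, query: float) -> float:
    """Upper-tail percent P(X >= query) for X ~ Normal(mean, sd)."""
    if sd <= 0:
        raise InvalidParameterError("sd must be > 0")
    return float(_norm.sf(query, loc=mean, scale=sd) * 100.0)
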