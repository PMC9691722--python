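"""Synthetic-data generators with known ground truth for every pipeline stage.

The generators emulate the study conditions of a positional-scanning
specificity screen of an HLA-A2-restricted nonamer:

* a 140-member scan library (7 varied positions x 20 amino acids, anchors
  p2=M / p9=V fixed, native peptide YMDGTMSQV measured in 7 replicates)
  whose substitution penalties are drawn per position class -- highly
  specific positions 3-6 (mean ddG 2.5 kcal/mol, SD 1.0) and tolerant
  positions 1, 7, 8 (mean 0.3, SD 0.3), truncated below at -0.2 kcal/mol so
  no variant substantially improves on wild type -- around a wild-type K_D
  of 25 uM;
* single-point SPR observations of that library on a paired
  reference/TCR surface at exchange-yield concentrations near 14 +/- 4 uM;
* two-state DSF melt curves on the 25-95 degC grid;
* toy proteomes with planted high-scoring nonamers;
* idealized pseudo-atom TCR-pMHC complexes realizing requested docking
  descriptors exactly.

All generators take an integer seed and are bit-reproducible; none touches
global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.stats import truncnorm

from .affinity import ReferenceSurface, langmuir_response
from .constants import AMINO_ACIDS, rt
from .dsf import MeltCurve
from .errors import InvalidParameterError
from .fingerprint import ANCHOR_POSITIONS, WT_SEQUENCE, ScanLibrary
from .geometry import ChainAnnotation, StructureComplex

__all__ = [
    "LibraryGroundTruth",
    "GeometryFixtureSpec",
    "gen_library",
    "gen_spr_observations",
    "gen_melt_curve",
    "gen_proteome",
    "gen_geometry_fixture",
    "write_structure",
]


@dataclass(frozen=True)
class LibraryGroundTruth:
    """Parameters of the synthetic scan-library landscape."""

    seed: int
    wt_kd: float = 2.5e-5  # molar
    specific_positions: tuple[int, ...] = (3, 4, 5, 6)
    specific_mean: float = 2.5  # kcal/mol ddG for substitutions
    specific_sd: float = 1.0
    tolerant_mean: float = 0.3
    tolerant_sd: float = 0.3
    ddg_floor: float = -0.2  # truncation: no substantial binding improvement
    noise: float = 0.04  # measurement error SD on dG, kcal/mol
    n_wt_replicates: int = 7
    wt_sequence: str = WT_SEQUENCE

    def __post_init__(self) -> None:
        if self.wt_kd <= 0 or self.wt_kd >= 1:
            raise InvalidParameterError("wt_kd must be in (0, 1) M")
        if self.specific_sd <= 0 or self.tolerant_sd <= 0:
            raise InvalidParameterError("effect SDs must be positive")
        if self.noise < 0:
            raise InvalidParameterError("noise must be >= 0")


def _trunc_draw(rng, mean: float, sd: float, floor: float, size: int) -> np.ndarray:
    a = (floor - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def gen_library(truth: LibraryGroundTruth) -> tuple[ScanLibrary, pd.DataFrame]:
    """Generate a complete scan library plus its underlying true dG table.

    Returns (library, truth_table); the truth table has one row per library
    member (position 0 rows are the wild-type replicates) with columns
    ``position, amino_acid, dg_true, dg_measured, kd_true``.
    """
    rng = np.random.default_rng(truth.seed)
    dg_wt = rt() * math.log(truth.wt_kd)
    varied = tuple(
        p for p in range(1, len(truth.wt_sequence) + 1) if p not in ANCHOR_POSITIONS
    )

    rows = []
    for pos in varied:
        native = truth.wt_sequence[pos - 1]
        if pos in truth.specific_positions:
            mean, sd = truth.specific_mean, truth.specific_sd
        else:
            mean, sd = truth.tolerant_mean, truth.tolerant_sd
        draws = _trunc_draw(rng, mean, sd, truth.ddg_floor, len(AMINO_ACIDS))
        for k, aa in enumerate(AMINO_ACIDS):
            ddg = 0.0 if aa == native else float(draws[k])
            dg_true = dg_wt + ddg
            dg_meas = dg_true + (rng.normal(0.0, truth.noise) if truth.noise else 0.0)
            rows.append((pos, aa, dg_true, dg_meas))
    for _ in range(truth.n_wt_replicates):
        dg_meas = dg_wt + (rng.normal(0.0, truth.noise) if truth.noise else 0.0)
        rows.append((0, "-", dg_wt, dg_meas))

    table = pd.DataFrame(rows, columns=["position", "amino_acid", "dg_true", "dg_measured"])
    table["kd_true"] = np.exp(table["dg_true"] / rt())

    members = table[table["position"] > 0]
    lib = ScanLibrary(
        entries=pd.DataFrame(
            {
                "position": members["position"].to_numpy(),
                "amino_acid": members["amino_acid"].to_numpy(),
                "dg": members["dg_measured"].to_numpy(),
                "dg_err": truth.noise,
            }
        ),
        wt_replicates=table.loc[table["position"] == 0, "dg_measured"].tolist(),
        wt_sequence=truth.wt_sequence,
    )
    return lib, table


def gen_spr_observations(
    truth_table: pd.DataFrame,
    ref: ReferenceSurface,
    rumax_tcr: float,
    noise_ru: float = 0.0,
    conc_mean: float = 14e-6,
    conc_sd: float = 4e-6,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-point SPR responses for every library member.

    Each sample gets an analyte concentration drawn near the exchange-yield
    scale (default 14 +/- 4 uM, truncated at one tenth of the mean), a
    reference-surface response from the calibrated Langmuir model, and a
    TCR-surface response from its true K_D, each plus Gaussian noise of SD
    ``noise_ru``.  Ground-truth columns are retained.
    """
    if rumax_tcr <= 0:
        raise InvalidParameterError("rumax_tcr must be > 0")
    if noise_ru < 0 or conc_sd < 0 or conc_mean <= 0:
        raise InvalidParameterError("invalid observation parameters")
    rng = np.random.default_rng(seed)
    floor = conc_mean / 10.0
    a = (floor - conc_mean) / conc_sd if conc_sd > 0 else 0.0

    out = []
    wt_counter = 0
    for row in truth_table.itertuples(index=False):
        if conc_sd > 0:
            c = float(truncnorm.rvs(a, np.inf, loc=conc_mean, scale=conc_sd,
                                    random_state=rng))
        else:
            c = conc_mean
        r_ref = langmuir_response(c, ref.kd_ref, ref.rumax_ref)
        r_tcr = langmuir_response(c, row.kd_true, rumax_tcr)
        if noise_ru:
            r_ref += rng.normal(0.0, noise_ru)
            r_tcr += rng.normal(0.0, noise_ru)
        if row.position == 0:
            wt_counter += 1
            sample_id = f"WT_{wt_counter}"
        else:
            sample_id = f"p{row.position}_{row.amino_acid}"
        out.append(
            (sample_id, row.position, row.amino_acid, row.kd_true, c, r_ref, r_tcr)
        )
    return pd.DataFrame(
        out,
        columns=[
            "sample_id", "position", "amino_acid",
            "true_kd_M", "true_conc_M", "r_ref_RU", "r_tcr_RU",
        ],
    )


def gen_melt_curve(
    tm: float,
    amplitude: float = 1000.0,
    baseline_intercept: float = 100.0,
    baseline_slope: float = 1.0,
    transition_width: float = 1.5,
    noise: float = 0.0,
    seed: int = 0,
    t_min: float = 25.0,
    t_max: float = 95.0,
    step: float = 1.0,
    sample_id: str = "",
) -> MeltCurve:
    """Two-state melt curve: linear baseline plus a logistic transition.

    F(T) = b0 + b1*T + A / (1 + exp(-(T - tm)/w)); the derivative of the
    noise-free curve peaks exactly at ``tm``, so on-grid melting points are
    recovered exactly by the derivative-maximum rule.
    """
    if not (t_min < tm < t_max):
        raise InvalidParameterError(
            f"tm={tm} outside the scan range ({t_min}, {t_max})"
        )
    if transition_width <= 0 or step <= 0:
        raise InvalidParameterError("transition_width and step must be > 0")
    t = np.arange(t_min, t_max + step / 2, step)
    f = (
        baseline_intercept
        + baseline_slope * t
        + amplitude / (1.0 + np.exp(-(t - tm) / transition_width))
    )
    if noise:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise, size=t.size)
    return MeltCurve(temperatures=t, fluorescence=f, sample_id=sample_id)


def gen_proteome(
    n_proteins: int = 20,
    length_range: tuple[int, int] = (200, 400),
    planted: list[tuple[str, int, int]] | None = None,
    seed: int = 0,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Random toy proteome with peptides planted verbatim at known offsets.

    ``planted`` holds (peptide, protein_index, offset) triples.  Returns the
    records and a manifest DataFrame (source_id, offset, peptide).
    """
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    if lo < 9 or hi < lo:
        raise InvalidParameterError("length_range must satisfy 9 <= lo <= hi")
    lengths = rng.integers(lo, hi + 1, size=n_proteins)
    seqs = [
        "".join(AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=n))
        for n in lengths
    ]
    manifest_rows = []
    for pep, pidx, off in planted or []:
        if not (0 <= pidx < n_proteins):
            raise InvalidParameterError(f"protein index {pidx} out of range")
        if off < 0 or off + len(pep) > len(seqs[pidx]):
            raise InvalidParameterError(
                f"planted peptide {pep!r} does not fit in protein {pidx} at {off}"
            )
        s = seqs[pidx]
        seqs[pidx] = s[:off] + pep.upper() + s[off + len(pep):]
        manifest_rows.append((f"synth_{pidx}", off, pep.upper()))
    records = [
        SeqRecord(Seq(s), id=f"synth_{i}", description="synthetic protein")
        for i, s in enumerate(seqs)
    ]
    manifest = pd.DataFrame(manifest_rows, columns=["source_id", "offset", "peptide"])
    return records, manifest


# ---------------------------------------------------------------------------
# geometry fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeometryFixtureSpec:
    """Target docking descriptors for a pseudo-atom TCR-pMHC complex."""

    seed: int = 0
    crossing_angle: float = 45.0  # degrees in (0, 180)
    com_angle: float = 60.0  # degrees in (0, 180)
    theta: float = 20.0  # degrees
    phi: float = 15.0  # degrees in [0, 90)
    r: float = 30.0  # Angstrom
    domain_half_separation: float = 10.0  # Angstrom between V-domain centers
    cluster_atoms: int = 24  # symmetric filler atoms per domain

    def __post_init__(self) -> None:
        if not (0.0 < self.crossing_angle < 180.0):
            raise InvalidParameterError("crossing_angle must be in (0, 180)")
        if not (0.0 < self.com_angle < 180.0):
            raise InvalidParameterError("com_angle must be in (0, 180)")
        if not (0.0 <= self.phi < 90.0):
            raise InvalidParameterError("phi must be in [0, 90)")
        if self.r <= 0:
            raise InvalidParameterError("r must be > 0")
        if self.cluster_atoms % 2:
            raise InvalidParameterError("cluster_atoms must be even")


def _domain_atoms(
    rng, center: np.ndarray, disulfide_centroid: np.ndarray, n_cluster: int
):
    """Pseudo-atom V domain with exact geometric center and one disulfide.

    The two CYS S-gamma atoms straddle ``disulfide_centroid``; every
    off-center atom has a mirror image through ``center`` so the domain's
    geometric center equals ``center`` exactly (up to float rounding).
    Yields (pos, element, atom_name, res_name) tuples; residues are numbered
    by the caller.
    """
    atoms = []
    half_bond = np.array([0.0, 0.0, 1.025])  # SG-SG distance 2.05 A
    for sign in (+1, -1):
        sg = disulfide_centroid + sign * half_bond
        atoms.append((sg, "S", "SG", "CYS"))
        atoms.append((2.0 * center - sg, "C", "CB", "ALA"))  # COM balance
    for _ in range(n_cluster // 2):
        offset = rng.normal(0.0, 3.0, size=3)
        atoms.append((center + offset, "C", "CA", "ALA"))
        atoms.append((center - offset, "C", "CA", "ALA"))
    return atoms


def gen_geometry_fixture(
    spec: GeometryFixtureSpec,
) -> tuple[StructureComplex, dict[str, float]]:
    """Build a pseudo-atom complex realizing the requested descriptors.

    The groove is a symmetric C-alpha grid in the z=0 plane (chain M,
    residues 1-180), the peptide a straight N->C trace along +x (chain P),
    and each V domain a mirror-symmetric atom cloud with one CYS disulfide
    (chains A and B).  Returns the complex and the dict of target values.
    """
    rng = np.random.default_rng(spec.seed)

    coords, elements, atom_names, res_numbers, res_names, chain_ids = (
        [], [], [], [], [], [],
    )

    def add(pos, element, name, resname, resnum, chain):
        coords.append(np.asarray(pos, dtype=float))
        elements.append(element)
        atom_names.append(name)
        res_numbers.append(resnum)
        res_names.append(resname)
        chain_ids.append(chain)

    # groove platform: 12 x 15 CA grid centered on the origin, z = 0
    xs = np.linspace(-22.0, 22.0, 12)
    ys = np.linspace(-14.0, 14.0, 15)
    resnum = 1
    for x in xs:
        for y in ys:
            add((x, y, 0.0), "C", "CA", "GLY", resnum, "M")
            resnum += 1

    # peptide: 9 CA along +x, slightly above the platform
    for i, x in enumerate(np.linspace(-4.0, 4.0, 9)):
        add((x, 0.0, 1.5), "C", "CA", "GLY", i + 1, "P")

    # TCR variable domains
    chi = math.radians(spec.crossing_angle)
    psi = math.radians(spec.com_angle)
    th = math.radians(spec.theta)
    ph = math.radians(spec.phi)
    center = spec.r * np.array(
        [math.sin(ph) * math.cos(th), math.sin(ph) * math.sin(th), math.cos(ph)]
    )
    u = np.array([math.cos(chi), math.sin(chi), 0.0])  # disulfide axis
    v = np.array([math.cos(psi), math.sin(psi), 0.0])  # COM axis
    half = spec.domain_half_separation

    for chain, sign in (("A", -1), ("B", +1)):
        dom_center = center + sign * half * v
        dom_ss = center + sign * half * u
        resnum = 1
        for pos, element, name, resname in _domain_atoms(
            rng, dom_center, dom_ss, spec.cluster_atoms
        ):
            add(pos, element, name, resname, resnum, chain)
            resnum += 1

    n_dom_res = spec.cluster_atoms + 4
    annotation = ChainAnnotation(
        tcr_alpha="A",
        tcr_beta="B",
        mhc_heavy="M",
        peptide="P",
        v_domain_ranges={"A": (1, n_dom_res), "B": (1, n_dom_res)},
        groove_range=(1, 180),
    )
    cx = StructureComplex(
        coords=np.vstack(coords),
        elements=np.array(elements, dtype=object),
        atom_names=np.array(atom_names, dtype=object),
        res_numbers=np.array(res_numbers, dtype=int),
        res_names=np.array(res_names, dtype=object),
        chain_ids=np.array(chain_ids, dtype=object),
        annotation=annotation,
    )
    targets = {
        "crossing_angle": spec.crossing_angle,
        "com_angle": spec.com_angle,
        "theta": spec.theta,
        "phi": spec.phi,
        "r": spec.r,
    }
    return cx, targets


def write_structure(cx: StructureComplex, path, fmt: str | None = None) -> None:
    """Write a StructureComplex to PDB or mmCIF (format from extension)."""
    import gemmi

    path = str(path)
    if fmt is None:
        fmt = "cif" if path.endswith((".cif", ".mmcif")) else "pdb"

    st = gemmi.Structure()
    st.name = "tcrspec-fixture"
    model = gemmi.Model("1")
    for chain_id in dict.fromkeys(cx.chain_ids):  # preserve insertion order
        chain = gemmi.Chain(str(chain_id))
        sel = np.flatnonzero(cx.chain_ids == chain_id)
        current_res = None
        res = None
        for i in sel:
            key = (int(cx.res_numbers[i]), str(cx.res_names[i]))
            if key != current_res:
                if res is not None:
                    chain.add_residue(res)
                res = gemmi.Residue()
                res.name = str(cx.res_names[i])
                res.seqid = gemmi.SeqId(int(cx.res_numbers[i]), " ")
                current_res = key
            atom = gemmi.Atom()
            atom.name = str(cx.atom_names[i])
            atom.element = gemmi.Element(str(cx.elements[i]).capitalize())
            atom.pos = gemmi.Position(*cx.coords[i])
            atom.occ = 1.0
            atom.b_iso = 20.0
            res.add_atom(atom)
        if res is not None:
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if fmt == "cif":
        st.make_mmcif_document().write_file(path)
    else:
        st.write_pdb(path)
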