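"""Positional-scanning specificity fingerprint (percent-response PWM).

A positional-scanning library of an anchored MHC class I nonamer (default
native peptide YMDGTMSQV, anchors p2=M and p9=V fixed) yields one measured
binding free energy dG(i, a) for every varied position i and amino acid a:
7 positions x 20 amino acids = 140 members, with the native peptide measured
in replicate.

The fingerprint rescales these free energies to a percent response in
[0, 100] per cell.  Orientation ``"strong-high"`` (the default) maps the
strongest binder (most negative dG) to 100 and the weakest to 0:

    percent(i, a) = 100 * (dg_weakest - dg(i, a)) / (dg_weakest - dg_strongest)

so that high scores mean strong binding.  The historically printed
orientation, 100*(dG - min)/(max - min) with min the strongest value, is
available as ``orientation="literal"`` for auditing; it inverts the scale.

A peptide matching the anchored motif is scored by summing its percent cells
over the 7 varied positions and dividing by the normalization factor (the
same sum evaluated on the native peptide), so the native peptide scores
exactly 1.  Scores map back to an estimated dissociation constant through

    K_D(s) = exp(s * dG_WT / RT) = K_D,WT ** s

which is anchored at s=1 -> K_D,WT and s=0 -> 1 M.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import AMINO_ACIDS, AA_INDEX, T_STANDARD_K, rt
from .errors import IncompleteLibraryError, InvalidParameterError, MotifError

__all__ = [
    "VARIED_POSITIONS",
    "ScanLibrary",
    "SpecificityFingerprint",
    "PeptideScore",
    "build_fingerprint",
    "score_peptide",
    "kd_from_score",
    "anchor_dg_wt",
    "read_library_csv",
    "write_library_csv",
]

WT_SEQUENCE = "YMDGTMSQV"
ANCHOR_POSITIONS = {2: "M", 9: "V"}
# 1-based peptide positions that are varied in the library (all but anchors).
VARIED_POSITIONS: tuple[int, ...] = (1, 3, 4, 5, 6, 7, 8)


@dataclass
class ScanLibrary:
    """Measured dG per (position, amino acid) of a positional-scanning library.

    Attributes
    ----------
    entries : pandas.DataFrame
        Columns ``position`` (1-based, in VARIED_POSITIONS), ``amino_acid``
        (one-letter), ``dg`` and ``dg_err`` (kcal/mol).
    wt_replicates : list of float
        Replicate dG measurements of the native peptide, kcal/mol.
    """

    entries: pd.DataFrame
    wt_replicates: list[float] = field(default_factory=list)
    wt_sequence: str = WT_SEQUENCE
    anchor_positions: dict[int, str] = field(
        default_factory=lambda: dict(ANCHOR_POSITIONS)
    )

    def __post_init__(self) -> None:
        varied = self.varied_positions
        df = self.entries
        required = {"position", "amino_acid", "dg"}
        if not required.issubset(df.columns):
            raise InvalidParameterError(
                f"library table must have columns {sorted(required)}"
            )
        if "dg_err" not in df.columns:
            df = df.assign(dg_err=0.0)
            self.entries = df
        bad_pos = set(df["position"]) - set(varied)
        if bad_pos:
            raise InvalidParameterError(
                f"entries at non-varied positions {sorted(bad_pos)} "
                f"(anchors {self.anchor_positions} are fixed)"
            )
        bad_aa = set(df["amino_acid"]) - set(AMINO_ACIDS)
        if bad_aa:
            raise InvalidParameterError(f"nonstandard amino acids {sorted(bad_aa)}")
        dup = df.duplicated(subset=["position", "amino_acid"])
        if dup.any():
            pairs = df.loc[dup, ["position", "amino_acid"]].values.tolist()
            raise InvalidParameterError(f"duplicate library cells: {pairs}")

    @property
    def varied_positions(self) -> tuple[int, ...]:
        return tuple(
            p for p in range(1, len(self.wt_sequence) + 1)
            if p not in self.anchor_positions
        )

    def missing_cells(self) -> list[tuple[int, str]]:
        have = set(zip(self.entries["position"], self.entries["amino_acid"]))
        return [
            (p, a)
            for p in self.varied_positions
            for a in AMINO_ACIDS
            if (p, a) not in have
        ]

    def is_complete(self) -> bool:
        return not self.missing_cells()

    def __len__(self) -> int:
        return len(self.entries)

    def dg_matrix(self) -> np.ndarray:
        """dG values as a (n_varied, 20) array, rows in position order."""
        missing = self.missing_cells()
        if missing:
            raise IncompleteLibraryError(
                f"library missing {len(missing)} cells: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        mat = np.empty((len(self.varied_positions), len(AMINO_ACIDS)))
        pos_row = {p: i for i, p in enumerate(self.varied_positions)}
        for p, a, dg in self.entries[["position", "amino_acid", "dg"]].itertuples(
            index=False
        ):
            mat[pos_row[p], AA_INDEX[a]] = dg
        return mat


@dataclass(frozen=True)
class SpecificityFingerprint:
    """Percent-response PWM with its normalization factor and WT anchor.

    ``percent`` is (n_varied, 20): rows follow ``varied_positions`` order,
    columns follow the alphabetical amino-acid order of ``AMINO_ACIDS``.
    """

    percent: np.ndarray
    norm_factor: float
    dg_wt: float
    dg_strongest: float
    dg_weakest: float
    wt_sequence: str = WT_SEQUENCE
    anchor_positions: dict[int, str] = field(
        default_factory=lambda: dict(ANCHOR_POSITIONS)
    )
    orientation: str = "strong-high"

    @property
    def varied_positions(self) -> tuple[int, ...]:
        return tuple(
            p for p in range(1, len(self.wt_sequence) + 1)
            if p not in self.anchor_positions
        )

    @property
    def kd_wt(self) -> float:
        return math.exp(self.dg_wt / rt(T_STANDARD_K))

    def max_score(self) -> float:
        """Largest achievable score (best cell at every varied position)."""
        return float(np.sum(np.max(self.percent, axis=1)) / self.norm_factor)

    def min_score(self) -> float:
        return float(np.sum(np.min(self.percent, axis=1)) / self.norm_factor)

    # ---- serialization -------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "percent": self.percent.tolist(),
            "norm_factor": self.norm_factor,
            "dg_wt": self.dg_wt,
            "dg_strongest": self.dg_strongest,
            "dg_weakest": self.dg_weakest,
            "wt_sequence": self.wt_sequence,
            "anchor_positions": {str(k): v for k, v in self.anchor_positions.items()},
            "orientation": self.orientation,
            "amino_acid_order": AMINO_ACIDS,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SpecificityFingerprint":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("amino_acid_order", AMINO_ACIDS) != AMINO_ACIDS:
            raise InvalidParameterError("unexpected amino-acid column order")
        return cls(
            percent=np.asarray(d["percent"], dtype=float),
            norm_factor=float(d["norm_factor"]),
            dg_wt=float(d["dg_wt"]),
            dg_strongest=float(d["dg_strongest"]),
            dg_weakest=float(d["dg_weakest"]),
            wt_sequence=d["wt_sequence"],
            anchor_positions={int(k): v for k, v in d["anchor_positions"].items()},
            orientation=d.get("orientation", "strong-high"),
        )


@dataclass(frozen=True)
class PeptideScore:
    peptide: str
    score: float
    est_kd: float


def build_fingerprint(
    lib: ScanLibrary,
    orientation: str = "strong-high",
    wt_cell_policy: str = "measured",
    dg_wt: float | None = None,
) -> SpecificityFingerprint:
    """Build the percent-response PWM from a complete scan library.

    Parameters
    ----------
    orientation : {"strong-high", "literal"}
        "strong-high" (default): strongest binder -> 100, weakest -> 0.
        "literal": the printed-formula orientation 100*(dG-min)/(max-min),
        which maps the strongest binder to 0; provided for audit only.
    wt_cell_policy : {"measured", "replicate-mean"}
        "measured" keeps each varied position's own native-cell measurement;
        "replicate-mean" substitutes the cross-replicate WT mean dG into all
        native cells before rescaling.
    dg_wt : float, optional
        dG anchor (kcal/mol, < 0) used by the score -> K_D conversion.
        Defaults to the mean of the library's WT replicates, falling back to
        the mean of the native cells if no replicates were recorded.
    """
    if orientation not in ("strong-high", "literal"):
        raise InvalidParameterError(f"unknown orientation {orientation!r}")
    if wt_cell_policy not in ("measured", "replicate-mean"):
        raise InvalidParameterError(f"unknown wt_cell_policy {wt_cell_policy!r}")

    mat = lib.dg_matrix()
    varied = lib.varied_positions
    wt_cols = [AA_INDEX[lib.wt_sequence[p - 1]] for p in varied]

    if wt_cell_policy == "replicate-mean":
        if not lib.wt_replicates:
            raise InvalidParameterError(
                "wt_cell_policy='replicate-mean' requires wt_replicates"
            )
        mat = mat.copy()
        wt_mean = float(np.mean(lib.wt_replicates))
        for row, col in enumerate(wt_cols):
            mat[row, col] = wt_mean

    strongest = float(mat.min())
    weakest = float(mat.max())
    if weakest <= strongest:
        raise InvalidParameterError(
            "degenerate library: all dG values equal; percent response undefined"
        )
    # divide before scaling so the extreme cells land exactly on 100 and 0
    if orientation == "strong-high":
        percent = 100.0 * ((weakest - mat) / (weakest - strongest))
    else:
        percent = 100.0 * ((mat - strongest) / (weakest - strongest))

    # Normalization factor: sum of the native-cell percents, accumulated in
    # ascending position order -- the same order score_peptide uses, so the
    # native peptide scores exactly 1.0.
    norm = 0.0
    for row, col in enumerate(wt_cols):
        norm += percent[row, col]
    if norm <= 0:
        raise InvalidParameterError(
            "normalization factor is non-positive; check orientation and library"
        )

    if dg_wt is None:
        if lib.wt_replicates:
            dg_wt = float(np.mean(lib.wt_replicates))
        else:
            dg_wt = float(np.mean([mat[r, c] for r, c in enumerate(wt_cols)]))

    return SpecificityFingerprint(
        percent=percent,
        norm_factor=float(norm),
        dg_wt=float(dg_wt),
        dg_strongest=strongest,
        dg_weakest=weakest,
        wt_sequence=lib.wt_sequence,
        anchor_positions=dict(lib.anchor_positions),
        orientation=orientation,
    )


def _validate_peptide(
    fp: SpecificityFingerprint, peptide: str, allowed_p2: set[str] | None
) -> None:
    n = len(fp.wt_sequence)
    if len(peptide) != n:
        raise MotifError(f"peptide must be {n} residues, got {len(peptide)}")
    bad = set(peptide) - set(AMINO_ACIDS)
    if bad:
        raise MotifError(f"nonstandard residues {sorted(bad)} in {peptide!r}")
    for pos, anchor_aa in fp.anchor_positions.items():
        allowed = {anchor_aa}
        if allowed_p2 is not None and pos == 2:
            allowed = set(allowed_p2)
        if peptide[pos - 1] not in allowed:
            raise MotifError(
                f"anchor mismatch at p{pos}: {peptide[pos - 1]!r} not in "
                f"{sorted(allowed)}"
            )


def score_peptide(
    fp: SpecificityFingerprint,
    peptide: str,
    allowed_p2: set[str] | None = None,
    temperature: float = T_STANDARD_K,
) -> PeptideScore:
    """Score a motif-matching peptide and estimate its K_D.

    The score is the sum of percent cells over the varied positions
    (ascending position order) divided by the normalization factor; anchor
    positions contribute nothing.  ``allowed_p2`` widens the accepted set at
    the p2 anchor (e.g. {"M", "L"}) without changing the score.
    """
    peptide = peptide.upper()
    _validate_peptide(fp, peptide, allowed_p2)
    total = 0.0
    for row, pos in enumerate(fp.varied_positions):
        total += fp.percent[row, AA_INDEX[peptide[pos - 1]]]
    s = total / fp.norm_factor
    return PeptideScore(
        peptide=peptide,
        score=float(s),
        est_kd=kd_from_score(s, fp.dg_wt, temperature),
    )


def kd_from_score(
    s: float, dg_wt: float, temperature: float = T_STANDARD_K
) -> float:
    """Estimated dissociation constant (molar) at fingerprint score s.

    K_D(s) = exp(s * dG_WT / RT) = K_D,WT**s; requires dG_WT < 0, giving a
    strictly decreasing map with K_D(0) = 1 M and K_D(1) = K_D,WT.
    """
    if dg_wt >= 0:
        raise InvalidParameterError(
            f"dg_wt must be negative (binding anchor), got {dg_wt}"
        )
    return math.exp(s * dg_wt / rt(temperature))


def anchor_dg_wt(
    score: float, kd_at_score: float, temperature: float = T_STANDARD_K
) -> float:
    """dG_WT implied by a known (score, K_D) pair: RT*ln(kd)/score."""
    if score <= 0:
        raise InvalidParameterError("anchoring score must be > 0")
    if kd_at_score <= 0 or kd_at_score >= 1.0:
        raise InvalidParameterError("anchoring kd must be in (0, 1) M")
    return rt(temperature) * math.log(kd_at_score) / score


# ---------------------------------------------------------------------------
# library I/O
# ---------------------------------------------------------------------------


def read_library_csv(
    path,
    wt_sequence: str = WT_SEQUENCE,
    temperature: float = T_STANDARD_K,
) -> ScanLibrary:
    """Read a scan library from CSV.

    Expected columns: ``position``, ``amino_acid``, and either
    ``dg_kcal_mol`` (with optional ``dg_err_kcal_mol``) or ``kd_M`` (with
    optional ``kd_err_M``, converted through dG = RT ln K_D).  Rows with
    position 0 are taken as wild-type replicate measurements.
    """
    df = pd.read_csv(path)
    if "dg_kcal_mol" in df.columns:
        dg = df["dg_kcal_mol"].astype(float)
        dg_err = df.get("dg_err_kcal_mol", pd.Series(0.0, index=df.index))
    elif "kd_M" in df.columns:
        kd = df["kd_M"].astype(float)
        dg = rt(temperature) * np.log(kd)
        kd_err = df.get("kd_err_M", pd.Series(0.0, index=df.index))
        dg_err = rt(temperature) * kd_err / kd
    else:
        raise InvalidParameterError(
            "library CSV needs a dg_kcal_mol or kd_M column"
        )
    table = pd.DataFrame(
        {
            "position": df["position"].astype(int),
            "amino_acid": df["amino_acid"].astype(str).str.upper(),
            "dg": dg.astype(float),
            "dg_err": np.asarray(dg_err, dtype=float),
        }
    )
    wt_mask = table["position"] == 0
    wt_replicates = table.loc[wt_mask, "dg"].tolist()
    return ScanLibrary(
        entries=table.loc[~wt_mask].reset_index(drop=True),
        wt_replicates=wt_replicates,
        wt_sequence=wt_sequence,
    )


def write_library_csv(lib: ScanLibrary, path) -> None:
    rows = lib.entries.rename(
        columns={"dg": "dg_kcal_mol", "dg_err": "dg_err_kcal_mol"}
    )
    wt = pd.DataFrame(
        {
            "position": 0,
            "amino_acid": "-",
            "dg_kcal_mol": lib.wt_replicates,
            "dg_err_kcal_mol": 0.0,
        }
    )
    pd.concat([rows, wt], ignore_index=True).to_csv(path, index=False)
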