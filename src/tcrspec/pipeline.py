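"""End-to-end orchestration: library -> fingerprint -> distribution report.

The fingerprint pipeline takes a scan-library table (or single-point SPR
observations reduced upstream), builds the percent-response PWM, computes
the exact score distribution over the anchored nonamer space, decile band
counts, logo matrices for requested bands, estimated affinities at
reference scores, and an optional proteome scan, and writes a
machine-readable JSON summary plus CSV/TSV side products.  Outputs are
deterministic for a fixed configuration; nothing is written until every
stage has succeeded.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .constants import T_STANDARD_K
from . import distribution as dist_mod
from .distribution import (
    band_count,
    count_at_or_above,
    distribution_moments,
    exact_score_distribution,
    logo_frequencies,
)
from .errors import TcrspecError
from .fingerprint import (
    ScanLibrary,
    build_fingerprint,
    kd_from_score,
    read_library_csv,
    score_peptide,
)
from .geometry import ChainAnnotation, docking_geometry, load_structure
from .proteome import scan_proteome

__all__ = [
    "RunConfig",
    "run_fingerprint_pipeline",
    "run_geometry_report",
    "annotation_from_dict",
]

REFERENCE_SCORES = (0.19, 0.5, 0.8, 0.95, 1.0)


@dataclass
class RunConfig:
    """Configuration of a fingerprint-pipeline run."""

    library_csv: str | None = None
    out_dir: str | None = None
    temperature: float = T_STANDARD_K
    orientation: str = "strong-high"  # or "literal"
    wt_cell_policy: str = "measured"
    dg_wt: float | None = None  # None: mean of library WT replicates
    bin_width: float = 0.01
    threshold: float = 0.8
    logo_bands: tuple[tuple[float, float], ...] = ((0.8, 0.9), (0.9, 1.0))
    reference_scores: tuple[float, ...] = REFERENCE_SCORES
    allowed_p2: tuple[str, ...] = ("M", "L")
    proteome_fasta: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _log(msg: str) -> None:
    print(f"[tcrspec] {msg}", file=sys.stderr)


def run_fingerprint_pipeline(
    cfg: RunConfig, library: ScanLibrary | None = None
) -> dict:
    """Run library -> fingerprint -> distribution -> report.

    ``library`` may be passed directly; otherwise ``cfg.library_csv`` is
    read.  Returns the summary dict; when ``cfg.out_dir`` is set, writes
    summary.json, fingerprint.json, distribution.csv, logo CSVs, optional
    proteome_hits.tsv, and the exact config used (config.json).
    """
    if library is None:
        if cfg.library_csv is None:
            raise TcrspecError("no library given (set library_csv or pass a library)")
        _log(f"reading library from {cfg.library_csv}")
        library = read_library_csv(cfg.library_csv, temperature=cfg.temperature)

    fp = build_fingerprint(
        library,
        orientation=cfg.orientation,
        wt_cell_policy=cfg.wt_cell_policy,
        dg_wt=cfg.dg_wt,
    )
    wt = score_peptide(fp, fp.wt_sequence, temperature=cfg.temperature)
    _log(f"fingerprint built: norm_factor={fp.norm_factor:.6g}, WT score={wt.score}")

    dist = exact_score_distribution(fp, bin_width=cfg.bin_width)
    moments = distribution_moments(dist)
    _log(
        f"score distribution: {dist.total} peptides, "
        f"mean={moments.mean:.4f}, sd={moments.sd:.4f}"
    )

    deciles = {
        f"{lo:.1f}-{lo + 0.1:.1f}": band_count(fp, lo, lo + 0.1)
        for lo in [k / 10.0 for k in range(0, 10)]
    }
    deciles[">=1.0"] = count_at_or_above(fp, 1.0)
    logos = {
        f"{lo:.2f}-{hi:.2f}": logo_frequencies(fp, lo, hi)
        for lo, hi in cfg.logo_bands
    }

    summary = {
        "config": cfg.to_dict(),
        "wt_sequence": fp.wt_sequence,
        "wt_score": wt.score,
        "norm_factor": fp.norm_factor,
        "dg_wt_kcal_mol": fp.dg_wt,
        "kd_wt_M": fp.kd_wt,
        "total_peptides": dist.total,
        "score_mean": moments.mean,
        "score_sd": moments.sd,
        "gaussian_fit": {
            "mean": moments.gauss_mean,
            "sd": moments.gauss_sd,
            "amplitude": moments.gauss_amplitude,
        },
        "count_at_or_above_threshold": count_at_or_above(fp, cfg.threshold),
        "threshold": cfg.threshold,
        "decile_counts": deciles,
        "est_kd_M_at_score": {
            str(s): kd_from_score(s, fp.dg_wt, cfg.temperature)
            for s in cfg.reference_scores
        },
        "logo_band_totals": {k: v.band_total for k, v in logos.items()},
    }

    scan = None
    if cfg.proteome_fasta:
        _log(f"scanning proteome {cfg.proteome_fasta}")
        scan = scan_proteome(
            fp,
            cfg.proteome_fasta,
            threshold=cfg.threshold,
            allowed_p2=set(cfg.allowed_p2),
            temperature=cfg.temperature,
        )
        summary["proteome"] = {
            "fasta": cfg.proteome_fasta,
            "threshold": cfg.threshold,
            "occurrences": len(scan.hits),
            "unique_peptides": scan.unique_peptides,
        }

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fp.to_json(out / "fingerprint.json")
        dist.to_csv(out / "distribution.csv")
        for name, logo in logos.items():
            logo.to_frame("counts").to_csv(out / f"logo_counts_{name}.csv")
            logo.to_frame("frequencies").to_csv(out / f"logo_freq_{name}.csv")
        if scan is not None:
            pd.DataFrame([dataclasses.asdict(h) for h in scan.hits]).to_csv(
                out / "proteome_hits.tsv", sep="\t", index=False
            )
        with open(out / "config.json", "w") as fh:
            json.dump(cfg.to_dict(), fh, indent=1, sort_keys=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        _log(f"report written to {out}")
    return summary


def annotation_from_dict(d: dict) -> ChainAnnotation:
    """Build a ChainAnnotation from a plain config mapping (JSON-friendly)."""
    return ChainAnnotation(
        tcr_alpha=d["tcr_alpha"],
        tcr_beta=d["tcr_beta"],
        mhc_heavy=d["mhc_heavy"],
        peptide=d["peptide"],
        beta2m=d.get("beta2m"),
        v_domain_ranges={
            k: tuple(v) for k, v in d.get("v_domain_ranges", {}).items()
        },
        groove_range=tuple(d.get("groove_range", (1, 180))),
        alpha2_helix_range=tuple(d.get("alpha2_helix_range", (138, 180))),
    )


def run_geometry_report(
    structures: list[tuple[str, ChainAnnotation]],
    out_path: str | None = None,
) -> pd.DataFrame:
    """Docking-geometry descriptors for a batch of structure files.

    Per-structure failures are logged to stderr and skipped; the returned
    table has one row per successful complex (duplicate paths are flagged).
    Writes a TSV when ``out_path`` is given.
    """
    rows = []
    seen: set[str] = set()
    failures = 0
    for path, ann in structures:
        duplicate = path in seen
        seen.add(path)
        try:
            cx = load_structure(path, ann)
            geo = docking_geometry(cx)
        except TcrspecError as exc:
            _log(f"skipping {path}: {exc}")
            failures += 1
            continue
        rows.append(
            {
                "structure": path,
                "crossing_angle_deg": geo.crossing_angle,
                "com_angle_deg": geo.com_angle,
                "theta_deg": geo.theta,
                "phi_deg": geo.phi,
                "r_A": geo.r,
                "canonical_polarity": geo.canonical_polarity,
                "duplicate": duplicate,
            }
        )
    if failures:
        _log(f"{failures} structure(s) failed")
    if not rows:
        _log("warning: empty geometry report")
    df = pd.DataFrame(
        rows,
        columns=[
            "structure", "crossing_angle_deg", "com_angle_deg",
            "theta_deg", "phi_deg", "r_A", "canonical_polarity", "duplicate",
        ],
    )
    if out_path:
        df.to_csv(out_path, sep="\t", index=False)
    return df
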