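"""Steady-state surface plasmon resonance (SPR) affinity analysis.

Implements the 1:1 Langmuir equilibrium binding model

    R_eq(C) = RU_max * C / (K_D + C)

and the operations built on it: titration fitting (independent or with a
shared RU_max across a group of titrations), the paired-surface single-point
assay in which the analyte concentration is first inferred from a
peptide-independent reference surface of known K_D and RU_max and then used
to solve for the K_D on the TCR surface, and the conversion between K_D and
standard binding free energy, dG = R*T*ln(K_D) (1 M standard state).

Measurement errors are propagated to first order (delta method) assuming
independent inputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import T_STANDARD_K, rt
from .errors import FitFailureError, InvalidParameterError, OutOfRangeError

__all__ = [
    "AffinityValue",
    "Titration",
    "BindingFit",
    "ReferenceSurface",
    "SinglePointResult",
    "langmuir_response",
    "fit_titration",
    "infer_concentration",
    "single_point_kd",
    "dg_from_kd",
    "kd_from_dg",
    "ddg_vs_wt",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AffinityValue:
    """A dissociation constant and its free-energy equivalent.

    Attributes
    ----------
    kd : float
        Dissociation constant in molar.
    dg : float
        Standard binding free energy, kcal/mol (negative for kd < 1 M).
    dg_err : float
        Propagated error on dg, kcal/mol.
    temperature : float
        Temperature in Kelvin used for the conversion.
    """

    kd: float
    dg: float
    dg_err: float = 0.0
    temperature: float = T_STANDARD_K

    @classmethod
    def from_kd(
        cls,
        kd: float,
        kd_err: float = 0.0,
        temperature: float = T_STANDARD_K,
    ) -> "AffinityValue":
        dg = dg_from_kd(kd, temperature)
        dg_err = rt(temperature) * (kd_err / kd) if kd_err else 0.0
        return cls(kd=kd, dg=dg, dg_err=dg_err, temperature=temperature)


@dataclass
class Titration:
    """One steady-state titration: responses at increasing concentrations.

    Duplicate injections belong in the same Titration (concatenated points);
    they are fit as a single dataset.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    replicate_group: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise InvalidParameterError(
                "concentrations and responses must have the same length"
            )
        if self.concentrations.size < 4:
            raise InvalidParameterError(
                f"need >=4 titration points for a well-posed fit, "
                f"got {self.concentrations.size}"
            )
        if np.any(self.concentrations <= 0):
            raise InvalidParameterError("concentrations must be strictly positive")


@dataclass(frozen=True)
class BindingFit:
    """Result of a 1:1 steady-state fit."""

    kd: float
    kd_err: float
    rumax: float
    rumax_err: float
    shared_rumax: bool
    residual_norm: float
    replicate_group: str = ""


@dataclass(frozen=True)
class ReferenceSurface:
    """Calibration of a peptide-independent reference surface (scTv-style)."""

    kd_ref: float
    kd_ref_err: float
    rumax_ref: float
    rumax_ref_err: float

    def __post_init__(self) -> None:
        for name in ("kd_ref", "kd_ref_err", "rumax_ref", "rumax_ref_err"):
            if getattr(self, name) < 0 or (
                name in ("kd_ref", "rumax_ref") and getattr(self, name) <= 0
            ):
                raise InvalidParameterError(f"{name} must be positive")


@dataclass(frozen=True)
class SinglePointResult:
    """Single-point K_D assay output with propagated errors."""

    concentration: float
    concentration_err: float
    kd: float
    kd_err: float
    dg: float
    dg_err: float
    temperature: float = T_STANDARD_K


# ---------------------------------------------------------------------------
# model and conversions
# ---------------------------------------------------------------------------


def langmuir_response(c, kd: float, rumax: float):
    """Equilibrium response of a 1:1 interaction: rumax*c/(kd + c).

    ``c`` may be a scalar or array (molar, >= 0); kd and rumax must be
    strictly positive.
    """
    if kd <= 0:
        raise InvalidParameterError(f"kd must be > 0, got {kd}")
    if rumax <= 0:
        raise InvalidParameterError(f"rumax must be > 0, got {rumax}")
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise InvalidParameterError("analyte concentration must be >= 0")
    out = rumax * c_arr / (kd + c_arr)
    return float(out) if np.isscalar(c) or c_arr.ndim == 0 else out


def dg_from_kd(kd: float, temperature: float = T_STANDARD_K) -> float:
    """Standard binding free energy dG = R*T*ln(kd), kcal/mol, kd in molar."""
    if kd <= 0:
        raise InvalidParameterError(f"kd must be > 0, got {kd}")
    return rt(temperature) * math.log(kd)


def kd_from_dg(dg: float, temperature: float = T_STANDARD_K) -> float:
    """Inverse of :func:`dg_from_kd`: kd = exp(dG/RT)."""
    return math.exp(dg / rt(temperature))


def ddg_vs_wt(dg: float, wt_replicates) -> float:
    """ddG relative to the mean of wild-type replicate dG values.

    Positive values mean weaker binding than wild type.
    """
    reps = np.asarray(wt_replicates, dtype=float)
    if reps.size == 0:
        raise InvalidParameterError("need at least one wild-type replicate")
    return float(dg - reps.mean())


# ---------------------------------------------------------------------------
# titration fitting
# ---------------------------------------------------------------------------


def _initial_guess(t: Titration) -> tuple[float, float]:
    # rumax0 a bit above the largest observed response; kd0 the concentration
    # at half of rumax0, interpolated on the sorted titration.
    rumax0 = 1.1 * float(np.max(t.responses))
    if rumax0 <= 0:
        raise FitFailureError("responses are non-positive; nothing to fit")
    order = np.argsort(t.concentrations)
    c_s = t.concentrations[order]
    r_s = t.responses[order]
    half = rumax0 / 2.0
    kd0 = float(np.interp(half, r_s, c_s, left=c_s[0], right=c_s[-1]))
    if kd0 <= 0:
        kd0 = float(np.median(c_s))
    return kd0, rumax0


def fit_titration(
    t: Titration | list[Titration],
    share: list[Titration] | None = None,
) -> BindingFit | list[BindingFit]:
    """Least-squares fit of 1:1 steady-state titrations.

    Parameters
    ----------
    t : Titration or list of Titration
        Dataset(s) to fit.  When ``share`` is given, ``t`` and ``share`` are
        pooled and fit globally with a single shared RU_max and one K_D per
        titration; otherwise each titration gets its own (kd, rumax).

    Returns
    -------
    BindingFit or list of BindingFit
        One fit per titration, in input order (``t`` first, then ``share``).
        Errors are 1-sigma values from the fit covariance.
    """
    single_input = isinstance(t, Titration)
    titrations: list[Titration] = [t] if single_input else list(t)
    shared = share is not None
    if shared:
        titrations = titrations + list(share)

    if not shared and len(titrations) > 1:
        return [fit_titration(ti) for ti in titrations]

    guesses = [_initial_guess(ti) for ti in titrations]
    # Parameters: log10(kd) per titration, then one log10(rumax) per titration
    # (or a single shared one).  Log scale enforces positivity and conditions
    # the problem across decades.
    n = len(titrations)
    kd0 = np.log10([g[0] for g in guesses])
    if shared:
        x0 = np.concatenate([kd0, [np.log10(max(g[1] for g in guesses))]])
    else:
        x0 = np.concatenate([kd0, [np.log10(guesses[0][1])]])

    def residuals(x: np.ndarray) -> np.ndarray:
        kds = 10.0 ** x[:n]
        rumax = 10.0 ** x[n]
        res = [
            ti.responses - rumax * ti.concentrations / (kds[i] + ti.concentrations)
            for i, ti in enumerate(titrations)
        ]
        return np.concatenate(res)

    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise FitFailureError(f"titration fit did not converge: {sol.message}")

    kds = 10.0 ** sol.x[:n]
    rumax = 10.0 ** sol.x[n]

    # Covariance from J^T J, scaled by residual variance.
    m = sol.fun.size
    p = sol.x.size
    dof = max(m - p, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        perr_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        perr_log = np.full(p, np.nan)
    ln10 = math.log(10.0)
    kd_errs = kds * ln10 * perr_log[:n]
    rumax_err = rumax * ln10 * perr_log[n]

    fits = []
    for i, ti in enumerate(titrations):
        pred = rumax * ti.concentrations / (kds[i] + ti.concentrations)
        if np.max(ti.responses) > 2.0 * rumax:
            warnings.warn(
                f"responses in group '{ti.replicate_group}' exceed twice the "
                f"fitted RU_max ({rumax:.3g}); check surface calibration",
                stacklevel=2,
            )
        fits.append(
            BindingFit(
                kd=float(kds[i]),
                kd_err=float(kd_errs[i]),
                rumax=float(rumax),
                rumax_err=float(rumax_err),
                shared_rumax=shared,
                residual_norm=float(np.linalg.norm(ti.responses - pred)),
                replicate_group=ti.replicate_group,
            )
        )
    return fits[0] if (single_input and not shared) else fits


# ---------------------------------------------------------------------------
# single-point assay
# ---------------------------------------------------------------------------


def infer_concentration(r_ref: float, ref: ReferenceSurface) -> tuple[float, float]:
    """Analyte concentration from a calibrated reference-surface response.

    Inverts the Langmuir model: C = kd_ref * r / (rumax_ref - r), with a
    first-order error from the reference kd and rumax uncertainties.

    Returns ``(concentration, concentration_err)`` in molar.
    """
    if r_ref <= 0:
        raise OutOfRangeError(
            f"reference response must be > 0 (no binding detected), got {r_ref}"
        )
    if r_ref >= ref.rumax_ref:
        raise OutOfRangeError(
            f"reference response {r_ref} RU is at or above RU_max "
            f"{ref.rumax_ref} RU (saturated/overrange signal)"
        )
    denom = ref.rumax_ref - r_ref
    c = ref.kd_ref * r_ref / denom
    # dC/dkd = r/(rumax - r); dC/drumax = -kd*r/(rumax - r)^2
    dc_dkd = r_ref / denom
    dc_drumax = -ref.kd_ref * r_ref / denom**2
    c_err = math.hypot(dc_dkd * ref.kd_ref_err, dc_drumax * ref.rumax_ref_err)
    return float(c), float(c_err)


def single_point_kd(
    r_tcr: float,
    c: float,
    c_err: float,
    rumax_tcr: float,
    rumax_tcr_err: float = 0.0,
    temperature: float = T_STANDARD_K,
) -> SinglePointResult:
    """K_D from one response at a known analyte concentration.

    Inverts the Langmuir model for kd: kd = c*(rumax - r)/r, then converts to
    dG with delta-method errors combining the concentration and RU_max
    uncertainties.
    """
    if rumax_tcr <= 0:
        raise InvalidParameterError("rumax_tcr must be > 0")
    if not (0 < r_tcr < rumax_tcr):
        raise OutOfRangeError(
            f"TCR-surface response {r_tcr} RU outside (0, RU_max={rumax_tcr})"
        )
    if c <= 0:
        raise InvalidParameterError("concentration must be > 0")
    kd = c * (rumax_tcr - r_tcr) / r_tcr
    dkd_dc = (rumax_tcr - r_tcr) / r_tcr
    dkd_drumax = c / r_tcr
    kd_err = math.hypot(dkd_dc * c_err, dkd_drumax * rumax_tcr_err)
    dg = dg_from_kd(kd, temperature)
    dg_err = rt(temperature) * kd_err / kd
    return SinglePointResult(
        concentration=float(c),
        concentration_err=float(c_err),
        kd=float(kd),
        kd_err=float(kd_err),
        dg=float(dg),
        dg_err=float(dg_err),
        temperature=temperature,
    )
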