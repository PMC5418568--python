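"""Rare-variant case-control association, inflation correction, and penetrance.

The association model is a logistic regression of case status on carrier
dosage; the slope exponentiates to the odds ratio, with Wald 95% intervals
and a Wald chi-square p-value. Genomic inflation from relatedness and
stratification is corrected by dividing the chi-square statistic by a
per-trait intercept factor (an LD-score-regression intercept supplied as
configuration). Odds ratios convert to carrier lifetime risks against a
registry baseline cumulative incidence at age 75, on either the odds scale
(carrier odds = OR x baseline odds) or a hazard scale
(risk = 1 - (1-K)^OR).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy import stats


@dataclass
class AssociationResult:
    variant_id: str
    cancer: str
    or_hat: float
    ci95: tuple[float, float]
    p_raw: float
    chi2_raw: float
    n_cases: int
    n_controls: int
    correction_factor: float = 1.0
    p_corrected: Optional[float] = None
    chi2_corrected: Optional[float] = None
    info: Optional[float] = None
    flagged: bool = False  # degenerate table / separation: bounds not finite

    def apply_correction(self, factor: float) -> "AssociationResult":
        chi2_c, p_c = correct_inflation(self.chi2_raw, factor)
        self.correction_factor = factor
        self.chi2_corrected = chi2_c
        self.p_corrected = p_c
        return self


def fit_association(
    genotype_dosage: np.ndarray,
    status: np.ndarray,
    variant_id: str = "",
    cancer: str = "",
) -> AssociationResult:
    """Logistic regression of case status on carrier dosage.

    Binary 0/1 dosages are aggregated to a weighted two-by-two design before
    fitting (the maximum-likelihood solution is unchanged); the estimate then
    equals the cross-product odds ratio. Degenerate tables (an empty margin
    or complete separation) return a flagged estimate with an infinite or
    zero bound rather than raising.

    Raises
    ------
    ValueError
        If there are no cases, no controls, or the dosage is constant.
    """
    dosage = np.asarray(genotype_dosage, dtype=float)
    y = np.asarray(status, dtype=float)
    if dosage.shape != y.shape:
        raise ValueError("dosage and status must be the same length")
    n_cases = int(y.sum())
    n_controls = int((1 - y).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("need at least one case and one control")
    if np.all(dosage == dosage[0]):
        raise ValueError("constant genotype dosage: association undefined")

    binary = np.isin(dosage, (0.0, 1.0)).all()
    if binary:
        a = float(((dosage == 1) & (y == 1)).sum())  # carrier cases
        b = float(((dosage == 1) & (y == 0)).sum())  # carrier controls
        c = float(((dosage == 0) & (y == 1)).sum())  # non-carrier cases
        d = float(((dosage == 0) & (y == 0)).sum())  # non-carrier controls
        if min(a, b, c, d) == 0.0:
            return _degenerate_result(a, b, variant_id, cancer,
                                      n_cases, n_controls)
        x = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 0.0], [1.0, 0.0]])
        yy = np.array([1.0, 0.0, 1.0, 0.0])
        w = np.array([a, b, c, d])
        model = sm.GLM(yy, x, family=sm.families.Binomial(), freq_weights=w)
    else:
        x = sm.add_constant(dosage)
        model = sm.GLM(y, x, family=sm.families.Binomial())
    fit = model.fit()
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    z = beta / se
    chi2 = z * z
    ci = (float(np.exp(beta - 1.959963984540054 * se)),
          float(np.exp(beta + 1.959963984540054 * se)))
    return AssociationResult(
        variant_id=variant_id,
        cancer=cancer,
        or_hat=float(np.exp(beta)),
        ci95=ci,
        p_raw=float(stats.chi2.sf(chi2, df=1)),
        chi2_raw=float(chi2),
        n_cases=n_cases,
        n_controls=n_controls,
    )


def _degenerate_result(a: float, b: float,
                       variant_id: str, cancer: str,
                       n_cases: int, n_controls: int) -> AssociationResult:
    """Flagged estimate for a two-by-two table with an empty cell."""
    if a == 0.0 and b == 0.0:
        raise ValueError("no carriers anywhere: association undefined")
    if b == 0.0:  # complete separation: every carrier is a case
        or_hat, ci = float("inf"), (0.0, float("inf"))
    elif a == 0.0:  # no carrier cases
        or_hat, ci = 0.0, (0.0, float("inf"))
    else:  # an empty non-carrier margin
        or_hat, ci = float("nan"), (0.0, float("inf"))
    return AssociationResult(
        variant_id=variant_id, cancer=cancer, or_hat=or_hat, ci95=ci,
        p_raw=float("nan"), chi2_raw=float("nan"),
        n_cases=n_cases, n_controls=n_controls, flagged=True,
    )


def correct_inflation(chi2_raw: float, factor: float) -> tuple[float, float]:
    """Divide a 1-df chi-square statistic by the inflation factor; return (chi2, p)."""
    if factor <= 0:
        raise ValueError("correction factor must be positive")
    chi2_c = chi2_raw / factor
    return chi2_c, float(stats.chi2.sf(chi2_c, df=1))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m for m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def format_sig3(x: float) -> str:
    """Format to three significant figures in scientific style, e.g. 3.13e-03."""
    return f"{x:.2e}"


def carrier_prevalence(freqs: dict[str, float] | list[float]) -> float:
    """Combined carrier prevalence of independent mutations: 1 - prod(1 - f)."""
    values = list(freqs.values()) if isinstance(freqs, dict) else list(freqs)
    for f in values:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"carrier frequency {f} outside [0,1]")
    return float(1.0 - np.prod([1.0 - f for f in values]))


def risk_from_or(or_val: float, baseline: float, formula: str = "odds_scale") -> float:
    """Carrier lifetime risk from an odds ratio and a baseline cumulative risk.

    odds_scale: carrier odds = OR x baseline odds, i.e.
    risk = OR*K / (1 - K + OR*K). hazard_scale: risk = 1 - (1-K)^OR. Both are
    monotone increasing in both arguments and return K at OR = 1.
    """
    if or_val <= 0:
        raise ValueError("odds ratio must be positive")
    if not 0.0 < baseline < 1.0:
        raise ValueError("baseline risk must lie in (0,1)")
    if formula == "odds_scale":
        return or_val * baseline / (1.0 - baseline + or_val * baseline)
    if formula == "hazard_scale":
        return 1.0 - (1.0 - baseline) ** or_val
    raise ValueError(f"unknown formula {formula!r}")


def baseline_from_risk(or_val: float, carrier_risk: float,
                       formula: str = "odds_scale") -> float:
    """Invert :func:`risk_from_or`: the baseline implied by a carrier risk."""
    if or_val <= 0:
        raise ValueError("odds ratio must be positive")
    if not 0.0 < carrier_risk < 1.0:
        raise ValueError("carrier risk must lie in (0,1)")
    if formula == "odds_scale":
        odds = carrier_risk / (1.0 - carrier_risk) / or_val
        return odds / (1.0 + odds)
    if formula == "hazard_scale":
        return 1.0 - (1.0 - carrier_risk) ** (1.0 / or_val)
    raise ValueError(f"unknown formula {formula!r}")


def imputation_concordance(imputed: np.ndarray, direct: np.ndarray) -> float:
    """Fraction of matching genotype calls; missing direct calls are excluded.

    Raises
    ------
    ValueError
        If the vectors differ in length or no direct calls overlap.
    """
    imputed = np.asarray(imputed, dtype=float)
    direct = np.asarray(direct, dtype=float)
    if imputed.shape != direct.shape:
        raise ValueError("imputed and direct call vectors must be paired")
    mask = ~np.isnan(direct)
    if not mask.any():
        raise ValueError("no overlapping direct calls: concordance undefined")
    return float(np.mean(imputed[mask] == direct[mask]))


# ---------------------------------------------------------------------------
# Retrospective case-control simulation
# ---------------------------------------------------------------------------


def case_carrier_freq(control_freq: float, true_or: float) -> float:
    """Expected carrier frequency among cases under the logistic model."""
    odds0 = control_freq / (1.0 - control_freq)
    odds1 = true_or * odds0
    return odds1 / (1.0 + odds1)


def simulate_case_control(
    n_cases: int,
    n_controls: int,
    carrier_freq: float,
    true_or: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw carrier dosages for fixed case/control totals (retrospective sampling).

    Controls carry at the population carrier frequency; cases carry at the
    frequency implied by the configured odds ratio. Returns (dosage, status).
    """
    f_case = case_carrier_freq(carrier_freq, true_or)
    case_dosage = (rng.random(n_cases) < f_case).astype(float)
    control_dosage = (rng.random(n_controls) < carrier_freq).astype(float)
    dosage = np.concatenate([case_dosage, control_dosage])
    status = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    return dosage, status
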