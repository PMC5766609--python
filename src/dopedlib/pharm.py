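"""Two-receptor pharmacology of phage-derived peptides.

Covers the peptide representation needed for engineered analogues
(D-residues, side-chain PK modifiers, C-terminal amide), EC50 ratio and
potency/balance classification of GCGR/GLP1R activity tables, the DPP-IV
cleavage liability, the standard lead-engineering transformations, and a
four-parameter-logistic dose-response fit for simulated cAMP readouts.

Conventions: EC50s are in nM; the agonism ratio is GCGR EC50 / GLP1R EC50
(ratio < 1 means more potent on GCGR); censored measurements (">20")
carry only their bound and are never imputed.  In serialized sequences a
lowercase letter is a D-residue and a parenthesized modifier follows its
residue letter, e.g. ``HsQGTFTSDK(γEγEC16)...``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .design import AMINO_ACIDS

__all__ = [
    "Residue",
    "PeptideSeq",
    "EC50",
    "ActivityRecord",
    "ClassificationParams",
    "Classification",
    "MODIFIER_VOCABULARY",
    "DEFAULT_ENGINEERING",
    "EngineeringRule",
    "ec50_ratio",
    "classify",
    "summarize_activity",
    "dppiv_liability",
    "apply_engineering",
    "DoseResponse",
    "DoseResponseResult",
    "four_parameter_logistic",
]

#: registered side-chain modifier strings (extend in place if needed)
MODIFIER_VOCABULARY: set[str] = {"γEγEC16"}


@dataclass(frozen=True)
class Residue:
    code: str            # 1-letter, uppercase
    d_form: bool = False
    modifier: str = ""

    def __post_init__(self):
        if self.code not in AMINO_ACIDS:
            raise ValueError(f"unknown residue code {self.code!r}")
        if self.modifier and self.modifier not in MODIFIER_VOCABULARY:
            raise ValueError(f"unregistered modifier {self.modifier!r}")

    def __str__(self) -> str:
        s = self.code.lower() if self.d_form else self.code
        return f"{s}({self.modifier})" if self.modifier else s


_TOKEN = re.compile(r"([A-Za-z])(\(([^)]+)\))?")


@dataclass(frozen=True)
class PeptideSeq:
    """A peptide with stereochemistry and side-chain modifiers."""

    residues: tuple[Residue, ...]
    c_term_amide: bool = True

    def __post_init__(self):
        object.__setattr__(self, "residues", tuple(self.residues))

    @classmethod
    def parse(cls, s: str, c_term_amide: bool = True) -> "PeptideSeq":
        s = s.replace(" ", "")
        residues = []
        pos = 0
        for m in _TOKEN.finditer(s):
            if m.start() != pos:
                raise ValueError(f"cannot parse sequence at {s[pos:]!r}")
            pos = m.end()
            ch, mod = m.group(1), m.group(3) or ""
            residues.append(Residue(code=ch.upper(), d_form=ch.islower(),
                                    modifier=mod))
        if pos != len(s):
            raise ValueError(f"cannot parse sequence at {s[pos:]!r}")
        return cls(residues=tuple(residues), c_term_amide=c_term_amide)

    def __str__(self) -> str:
        return "".join(str(r) for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def backbone(self) -> str:
        """Plain uppercase sequence (stereochemistry/modifiers dropped)."""
        return "".join(r.code for r in self.residues)

    @property
    def is_plain(self) -> bool:
        return all(not r.d_form and not r.modifier for r in self.residues)


@dataclass(frozen=True)
class EC50:
    """One EC50 measurement (nM): mean ± sd, or a censored lower bound."""

    mean: float | None = None
    sd: float | None = None
    censor_bound: float | None = None  # ">bound": no potency reached

    def __post_init__(self):
        if self.censor_bound is None:
            if self.mean is None or self.mean <= 0:
                raise ValueError("uncensored EC50 needs a positive mean")
        elif self.mean is not None:
            raise ValueError("censored EC50 carries only its bound")

    @property
    def is_censored(self) -> bool:
        return self.censor_bound is not None

    @classmethod
    def parse(cls, text: str, sd: str | float | None = None) -> "EC50":
        text = str(text).strip()
        if text.startswith(">"):
            return cls(censor_bound=float(text[1:]))
        sd_val = None if sd in (None, "") else float(sd)
        return cls(mean=float(text), sd=sd_val)

    def __str__(self) -> str:
        if self.is_censored:
            return f">{self.censor_bound:g}"
        if self.sd is not None:
            return f"{self.mean:g} ± {self.sd:g}"
        return f"{self.mean:g}"


@dataclass(frozen=True)
class ActivityRecord:
    """Per-peptide two-receptor activity (GCGR and GLP1R EC50s, nM)."""

    peptide_id: str
    sequence: PeptideSeq
    gcgr: EC50
    glp1r: EC50


@dataclass(frozen=True)
class ClassificationParams:
    """Potency and balance thresholds, all inclusive.

    ``potency_tiers`` are the per-receptor EC50 cutoffs (nM) defining the
    top co-agonist tiers (defaults 30 pM and 80 pM); ``balance_window``
    bounds the GCGR/GLP1R EC50 ratio called balanced; EC50 above
    ``inactivity_bound`` (or censored) counts as inactive on a receptor.
    """

    potency_tiers: tuple[float, ...] = (0.030, 0.080)
    balance_window: tuple[float, float] = (0.5, 1.5)
    inactivity_bound: float = 20.0

    def __post_init__(self):
        if any(t <= 0 for t in self.potency_tiers):
            raise ValueError("potency thresholds must be positive")
        lo, hi = self.balance_window
        if lo > hi:
            raise ValueError("balance window lower bound above upper")


@dataclass(frozen=True)
class Classification:
    tier: str                  # inactive | single-agonist | co-agonist-biased
    #                          # | co-agonist-balanced
    direction: str | None      # receptor for single/biased tiers
    potency_tier: str          # e.g. "<=0.03nM", "<=0.08nM", "other"
    ratio: float | None        # GCGR/GLP1R; None when censored


def ec50_ratio(record: ActivityRecord) -> float | None:
    """GCGR EC50 / GLP1R EC50; None (undefined) if either side censored."""
    if record.gcgr.is_censored or record.glp1r.is_censored:
        return None
    if record.gcgr.mean <= 0 or record.glp1r.mean <= 0:
        raise ValueError("EC50 means must be positive")
    return record.gcgr.mean / record.glp1r.mean


def _passes(ec: EC50, threshold: float) -> bool:
    """Inclusive threshold; a censored value exceeds any finite one."""
    return (not ec.is_censored) and ec.mean <= threshold


def classify(record: ActivityRecord,
             params: ClassificationParams = ClassificationParams(),
             ) -> Classification:
    """Assign a peptide to its agonism tier.

    Tiers: inactive (neither receptor activated within the inactivity
    bound), single-agonist (one receptor), co-agonist-balanced (ratio in
    the balance window, endpoints inclusive) or co-agonist-biased toward
    the more potently activated receptor.
    """
    active_gcgr = _passes(record.gcgr, params.inactivity_bound)
    active_glp1r = _passes(record.glp1r, params.inactivity_bound)
    ratio = ec50_ratio(record)

    both = active_gcgr and active_glp1r
    tiers = sorted(params.potency_tiers)
    potency = "other"
    if both:
        for t in tiers:
            if _passes(record.gcgr, t) and _passes(record.glp1r, t):
                potency = f"<={t:g}nM"
                break

    if not active_gcgr and not active_glp1r:
        return Classification("inactive", None, "other", ratio)
    if not both:
        direction = "GCGR" if active_gcgr else "GLP1R"
        return Classification("single-agonist", direction, "other", ratio)
    lo, hi = params.balance_window
    assert ratio is not None  # both sides uncensored here
    if lo <= ratio <= hi:
        return Classification("co-agonist-balanced", None, potency, ratio)
    direction = "GCGR" if ratio < lo else "GLP1R"
    return Classification("co-agonist-biased", direction, potency, ratio)


def summarize_activity(records: Sequence[ActivityRecord],
                       params: ClassificationParams = ClassificationParams(),
                       ) -> dict:
    """Tier counts over an activity table.

    Also reports, for each potency tier, how many peptides pass on both
    receptors; the number of rows with undefined (censored) ratio; and
    the balance-window count for both ratio directions, since the ratio
    convention is ambiguous in the field.
    """
    if not records:
        raise ValueError("empty activity table")
    out: dict = {"n": len(records)}
    tier_counts: dict[str, int] = {}
    for rec in records:
        c = classify(rec, params)
        key = c.tier if c.direction is None else f"{c.tier}({c.direction})"
        tier_counts[key] = tier_counts.get(key, 0) + 1
    out["tiers"] = dict(sorted(tier_counts.items()))
    for t in sorted(params.potency_tiers):
        out[f"both_le_{t:g}nM"] = sum(
            _passes(r.gcgr, t) and _passes(r.glp1r, t) for r in records)
    out["undefined_ratio"] = sum(ec50_ratio(r) is None for r in records)
    lo, hi = params.balance_window
    ratios = [ec50_ratio(r) for r in records]
    out["balanced_gcgr_over_glp1r"] = sum(
        r is not None and lo <= r <= hi for r in ratios)
    out["balanced_glp1r_over_gcgr"] = sum(
        r is not None and lo <= 1.0 / r <= hi for r in ratios)
    return out


def dppiv_liability(peptide: PeptideSeq) -> tuple[bool, str]:
    """DPP-IV cleaves after residue 2 of a free N-terminus when residue 2
    is L-configured Ser, Ala or Pro; a D-residue at position 2 blocks it."""
    if len(peptide) < 2:
        raise ValueError("peptide must have >= 2 residues")
    r2 = peptide.residues[1]
    if r2.code in ("S", "A", "P") and not r2.d_form:
        return True, (f"{peptide.residues[0].code}1-{r2.code}2 "
                      "DPP-IV cleavage site")
    if r2.d_form:
        return False, f"position 2 is D-{r2.code} (protected)"
    return False, f"position 2 is {r2.code} (not S/A/P)"


@dataclass(frozen=True)
class EngineeringRule:
    """Replace the residue at ``position`` (1-based)."""

    position: int
    code: str | None = None
    d_form: bool | None = None
    modifier: str | None = None


#: stabilize against DPP-IV and install the γGlu-γGlu-C16 PK modifier on a
#: Lys substituted at position 10
DEFAULT_ENGINEERING: tuple[EngineeringRule, ...] = (
    EngineeringRule(position=2, code="S", d_form=True),
    EngineeringRule(position=10, code="K", modifier="γEγEC16"),
)


def apply_engineering(peptide: PeptideSeq,
                      rules: Iterable[EngineeringRule] = DEFAULT_ENGINEERING,
                      ) -> PeptideSeq:
    """Apply residue-level engineering rules; length and untouched
    residues are preserved."""
    residues = list(peptide.residues)
    for rule in rules:
        i = rule.position - 1
        if not 0 <= i < len(residues):
            raise ValueError(f"rule targets absent position {rule.position}")
        old = residues[i]
        residues[i] = Residue(
            code=old.code if rule.code is None else rule.code,
            d_form=old.d_form if rule.d_form is None else rule.d_form,
            modifier=old.modifier if rule.modifier is None else rule.modifier,
        )
    return PeptideSeq(residues=tuple(residues),
                      c_term_amide=peptide.c_term_amide)


# ---------------------------------------------------------------------------
# dose-response fitting

def four_parameter_logistic(dose, bottom, top, log10_ec50, hill):
    """4PL response: bottom + (top-bottom) / (1 + (EC50/dose)^hill)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (
        1.0 + 10.0 ** (hill * (log10_ec50 - np.log10(dose))))


@dataclass
class DoseResponseResult:
    """Fitted 4PL parameters with standard errors and a summary table."""

    params: dict
    se: dict
    converged: bool
    n_obs: int
    residual_sd: float

    @property
    def ec50(self) -> float:
        return 10.0 ** self.params["log10_ec50"]

    def ec50_ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        lo = self.params["log10_ec50"] - z * self.se["log10_ec50"]
        hi = self.params["log10_ec50"] + z * self.se["log10_ec50"]
        return 10.0 ** lo, 10.0 ** hi

    def summary(self) -> str:
        lines = ["Four-parameter logistic fit",
                 f"  n obs:      {self.n_obs}",
                 f"  converged:  {self.converged}",
                 f"  residual sd {self.residual_sd:.4g}"]
        for k in ("bottom", "top", "log10_ec50", "hill"):
            lines.append(f"  {k:<11} {self.params[k]: .4g}"
                         f"  (se {self.se[k]:.3g})")
        if self.converged:
            lo, hi = self.ec50_ci()
            lines.append(f"  EC50        {self.ec50:.4g} nM"
                         f"  [95% CI {lo:.4g}, {hi:.4g}]")
        return "\n".join(lines)


class DoseResponse:
    """Four-parameter logistic dose-response model.

    ``fit()`` estimates (bottom, top, log10 EC50, hill) by nonlinear
    least squares; a flat or non-identifiable response is returned with
    ``converged=False`` rather than raised.
    """

    def __init__(self, doses: Sequence[float], responses: Sequence[float]):
        doses = np.asarray(doses, dtype=float)
        responses = np.asarray(responses, dtype=float)
        if doses.shape != responses.shape:
            raise ValueError("doses and responses differ in shape")
        if doses.size < 5:
            raise ValueError("need >= 5 dose points")
        if np.any(doses <= 0):
            raise ValueError("doses must be positive")
        self.doses = doses
        self.responses = responses

    def fit(self) -> DoseResponseResult:
        from scipy.optimize import curve_fit

        y = self.responses
        span = float(y.max() - y.min())
        p0 = [float(y.min()), float(y.max()),
              float(np.mean(np.log10(self.doses))), 1.0]
        nan_se = {k: float("nan")
                  for k in ("bottom", "top", "log10_ec50", "hill")}
        if span <= 0 or span < 1e-12 * max(1.0, abs(float(y.mean()))):
            params = dict(zip(nan_se, p0))
            return DoseResponseResult(params=params, se=nan_se,
                                      converged=False, n_obs=y.size,
                                      residual_sd=float(np.std(y)))
        try:
            popt, pcov = curve_fit(four_parameter_logistic, self.doses, y,
                                   p0=p0, maxfev=20000)
        except RuntimeError:
            params = dict(zip(nan_se, p0))
            return DoseResponseResult(params=params, se=nan_se,
                                      converged=False, n_obs=y.size,
                                      residual_sd=float(np.std(y)))
        names = ("bottom", "top", "log10_ec50", "hill")
        params = dict(zip(names, (float(v) for v in popt)))
        diag = np.diag(pcov)
        se = dict(zip(names,
                      (float(math.sqrt(v)) if np.isfinite(v) and v >= 0
                       else float("nan") for v in diag)))
        resid = y - four_parameter_logistic(self.doses, *popt)
        converged = bool(np.all(np.isfinite(popt)))
        # an EC50 outside the tested dose range is not identified
        if not (np.log10(self.doses).min() - 1 <= params["log10_ec50"]
                <= np.log10(self.doses).max() + 1):
            converged = False
        return DoseResponseResult(params=params, se=se, converged=converged,
                                  n_obs=y.size,
                                  residual_sd=float(np.std(resid)))


def fit_dose_response(doses, responses) -> DoseResponseResult:
    """Convenience wrapper: ``DoseResponse(doses, responses).fit()``."""
    return DoseResponse(doses, responses).fit()
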