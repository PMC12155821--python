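"""Equivalence and known-group statistics for tapping outcomes.

Two measurement systems are compared with an equivalence test: a linear
mixed model (fixed effects: system, and group when present; random
intercepts for participant and for trial within participant) estimates the
systematic between-system difference, which is then subjected to two
one-sided tests (TOST) against bounds of +/-5 % of the reference system's
grand mean. The reported equivalence p-value is the larger of the two
one-sided p-values, so p < alpha declares equivalence within the margin.

Known-group validity (healthy controls vs the patient group) uses a mixed
model with a group fixed effect and participant random intercepts, plus
Hedges' g with the small-sample correction on participant-level data
collapsed across hands.

Mixed-model fitting delegates to statsmodels; this module contributes the
TOST construction, margin anchoring, pairing validation, and reporting.
Fixed-effect tests use t references with containment-style denominator
degrees of freedom (between-participant df for the group effect, residual
df for the within-participant system effect), labeled in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import ContractError

REFERENCE_SYSTEM = "reference"
CANDIDATE_SYSTEM = "candidate"


@dataclass
class EquivalenceResult:
    """TOST equivalence outcome for one metric between two systems."""

    outcome: str
    reference_mean: float
    candidate_mean: float
    percent_difference: float
    margin: float  # half-width, metric units
    system_effect: float  # candidate - reference, mixed-model estimate
    system_se: float
    p_equivalence: float
    df: float
    df_method: str
    converged: bool


@dataclass
class GroupResult:
    """Known-group comparison outcome for one metric."""

    outcome: str
    hc_mean: float
    hc_sd: float
    pd_mean: float
    pd_sd: float
    group_effect: float  # PD - HC, mixed-model estimate
    hedges_g: float
    p_value: float
    df: float
    df_method: str
    converged: bool


def percent_difference(candidate_mean: float, reference_mean: float) -> float:
    """Percent difference of the candidate from the reference mean.

    ``100 * (candidate - reference) / reference``; display rounding to one
    decimal is left to the caller.
    """
    if reference_mean == 0:
        raise ContractError("reference mean must be nonzero")
    return 100.0 * (candidate_mean - reference_mean) / reference_mean


def hedges_g(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Hedges' g of b relative to a: pooled-SD standardized mean
    difference with the small-sample correction J = 1 - 3/(4(na+nb)-9)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ContractError("both groups need at least two values")
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ContractError("zero pooled standard deviation")
    j = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float(j * (b.mean() - a.mean()) / np.sqrt(pooled_var))


def _validate_long(df: pd.DataFrame, required: tuple[str, ...]) -> pd.DataFrame:
    missing = set(required) - set(df.columns)
    if missing:
        raise ContractError(f"records missing columns {sorted(missing)}")
    out = df.copy()
    out = out.dropna(subset=["value"])
    # statsmodels aligns rows by index; concatenated inputs may carry
    # duplicate labels, so renumber defensively
    return out.reset_index(drop=True)


def _fit_mixedlm(formula: str, data: pd.DataFrame, vc_formula=None):
    """REML fit with convergence-warning suppression; returns (fit, ok)."""
    model = smf.mixedlm(
        formula, data, groups=data["participant"], vc_formula=vc_formula,
        re_formula="1",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            fit = model.fit(reml=True, method="lbfgs", maxiter=200)
        except (np.linalg.LinAlgError, ValueError):
            return None, False
    ok = bool(getattr(fit, "converged", True)) and np.isfinite(fit.params).all()
    return fit, ok


def equivalence_test(
    records: pd.DataFrame,
    outcome: str = "value",
    margin_frac: float = 0.05,
) -> EquivalenceResult:
    """Test equivalence of a candidate system to the reference system.

    ``records`` is long-format with columns ``participant``, ``trial``,
    ``system`` (``reference`` / ``candidate``), ``value``, and optionally
    ``group``. Every (participant, trial) must be measured by both
    systems. The equivalence bounds are +/- ``margin_frac`` times the
    reference grand mean; the mixed model has fixed effects for system
    (and group when it varies) and random intercepts for participant and
    trial-within-participant.
    """
    if margin_frac <= 0:
        raise ContractError("equivalence margin must be positive")
    df = _validate_long(records, ("participant", "trial", "system", "value"))
    systems = set(df["system"].unique())
    if systems != {REFERENCE_SYSTEM, CANDIDATE_SYSTEM}:
        raise ContractError(
            f"expected systems {{{REFERENCE_SYSTEM!r}, {CANDIDATE_SYSTEM!r}}}, "
            f"got {sorted(systems)}"
        )
    counts = df.groupby(["participant", "trial"])["system"].nunique()
    if (counts < 2).any():
        raise ContractError("unpaired data: every (participant, trial) needs both systems")
    if df["participant"].nunique() < 2:
        raise ContractError("need at least two participants")

    ref_mean = float(df.loc[df["system"] == REFERENCE_SYSTEM, "value"].mean())
    cand_mean = float(df.loc[df["system"] == CANDIDATE_SYSTEM, "value"].mean())
    margin = margin_frac * abs(ref_mean)
    if margin == 0:
        raise ContractError("reference grand mean is zero; margin undefined")

    formula = f"value ~ C(system, Treatment('{REFERENCE_SYSTEM}'))"
    if "group" in df.columns and df["group"].nunique() > 1:
        formula += " + C(group)"
    data = df.copy()
    data["trial"] = data["trial"].astype(str)
    fit, ok = _fit_mixedlm(formula, data, vc_formula={"trial": "0 + C(trial)"})

    term = f"C(system, Treatment('{REFERENCE_SYSTEM}'))[T.{CANDIDATE_SYSTEM}]"
    if fit is None:
        return EquivalenceResult(
            outcome, ref_mean, cand_mean,
            percent_difference(cand_mean, ref_mean), margin,
            float("nan"), float("nan"), float("nan"), float("nan"),
            "residual", False,
        )
    beta = float(fit.params[term])
    se = float(fit.bse[term])
    # within-participant effect: residual df after fixed effects and
    # participant intercepts (containment approximation)
    k_fixed = len(fit.fe_params)
    dof = max(len(data) - data["participant"].nunique() - k_fixed, 1)
    # TOST: H01: beta <= -margin, H02: beta >= +margin
    t_lower = (beta + margin) / se
    t_upper = (beta - margin) / se
    p_lower = float(spstats.t.sf(t_lower, dof))
    p_upper = float(spstats.t.cdf(t_upper, dof))
    return EquivalenceResult(
        outcome=outcome,
        reference_mean=ref_mean,
        candidate_mean=cand_mean,
        percent_difference=percent_difference(cand_mean, ref_mean),
        margin=margin,
        system_effect=beta,
        system_se=se,
        p_equivalence=max(p_lower, p_upper),
        df=float(dof),
        df_method="residual",
        converged=ok,
    )


def known_group_test(
    records: pd.DataFrame, outcome: str = "value"
) -> GroupResult:
    """Compare HC and PD groups for one outcome with a mixed model.

    ``records`` is long-format with columns ``participant``, ``group``
    (``HC`` / ``PD``), ``value``. The model has a group fixed effect and
    participant random intercepts. Descriptive means/SDs and Hedges' g
    use participant-level values collapsed across trials/hands.
    """
    df = _validate_long(records, ("participant", "group", "value"))
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ContractError(f"need exactly two groups, got {groups}")
    per_part = df.groupby("participant")["group"].nunique()
    if (per_part > 1).any():
        raise ContractError("each participant must belong to one group")

    # participant-level collapse for descriptives and effect size
    collapsed = df.groupby(["participant", "group"], sort=True)["value"].mean().reset_index()
    hc = collapsed.loc[collapsed["group"] == "HC", "value"].to_numpy()
    pdv = collapsed.loc[collapsed["group"] == "PD", "value"].to_numpy()
    if len(hc) == 0 or len(pdv) == 0:
        raise ContractError("groups must be labeled 'HC' and 'PD'")

    fit, ok = _fit_mixedlm("value ~ C(group, Treatment('HC'))", df)
    term = "C(group, Treatment('HC'))[T.PD]"
    if fit is None:
        beta, se, p, dof = float("nan"), float("nan"), float("nan"), float("nan")
    else:
        beta = float(fit.params[term])
        se = float(fit.bse[term])
        # group is a between-participant effect: containment df
        dof = max(df["participant"].nunique() - 2, 1)
        p = float(2.0 * spstats.t.sf(abs(beta / se), dof))
    return GroupResult(
        outcome=outcome,
        hc_mean=float(hc.mean()),
        hc_sd=float(hc.std(ddof=1)) if len(hc) > 1 else float("nan"),
        pd_mean=float(pdv.mean()),
        pd_sd=float(pdv.std(ddof=1)) if len(pdv) > 1 else float("nan"),
        group_effect=beta,
        hedges_g=hedges_g(hc, pdv),
        p_value=p,
        df=float(dof),
        df_method="containment",
        converged=ok,
    )


def equivalence_table(
    records: pd.DataFrame,
    outcomes: list[str] | None = None,
    margin_frac: float = 0.05,
) -> pd.DataFrame:
    """Run :func:`equivalence_test` per metric on a long table with a
    ``metric`` column; returns one row per outcome."""
    if "metric" not in records.columns:
        raise ContractError("records need a 'metric' column")
    outcomes = outcomes or sorted(records["metric"].unique())
    rows = []
    for name in outcomes:
        sub = records.loc[records["metric"] == name]
        res = equivalence_test(sub, outcome=name, margin_frac=margin_frac)
        rows.append(vars(res))
    return pd.DataFrame(rows)


def known_group_table(
    records: pd.DataFrame, outcomes: list[str] | None = None
) -> pd.DataFrame:
    """Run :func:`known_group_test` per metric; one row per outcome."""
    if "metric" not in records.columns:
        raise ContractError("records need a 'metric' column")
    outcomes = outcomes or sorted(records["metric"].unique())
    rows = []
    for name in outcomes:
        sub = records.loc[records["metric"] == name]
        res = known_group_test(sub, outcome=name)
        rows.append(vars(res))
    return pd.DataFrame(rows)
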