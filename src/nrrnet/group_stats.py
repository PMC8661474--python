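"""Per-feature patient-vs-control tests and the medication confounder scan.

Group differences are assessed feature-by-feature with one-way ANOVA
followed by Tukey's HSD. With exactly two groups, the studentized-range
statistic satisfies q = sqrt(2)*|t|, so the Tukey p-value coincides with
the pooled two-sample t-test p — the implementation uses that identity
exactly for k = 2 and the studentized-range distribution for k >= 3.

The confounder scan asks whether any measured feature tracks antipsychotic
medication among the patients: an ordinary (Gaussian, identity-link) linear
model of the processed value on the binary medication flag, with
Benjamini-Hochberg and Bonferroni corrections computed side by side across
all features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FeatureTable, SampleMetadata, ValidationError
from .preprocess import clean_nonpositive, impute_half_minimum

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class GroupTestResult:
    feature_id: str
    mean_patient: float
    mean_control: float
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValidationError(f"p-value out of [0,1]: {self.p_value}")
        if self.significant != (self.p_value < ALPHA):
            raise ValidationError("significance flag inconsistent with p < 0.05")


@dataclass(frozen=True)
class ConfounderScanResult:
    feature_id: str
    coefficient: float
    p_raw: float
    p_bh: float
    p_bonferroni: float
    flagged: bool


# ---------------------------------------------------------------------------
# Tukey HSD


def tukey_hsd(groups: Sequence[Sequence[float]]) -> np.ndarray:
    """All-pairs Tukey HSD p-values after one-way ANOVA.

    Returns a k x k symmetric matrix (diagonal 1). Uses the Tukey-Kramer
    statistic q = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)) against
    the studentized-range distribution with k groups and N - k error df;
    for k = 2 the exact pooled-t identity is used instead.
    """
    arrays = [np.asarray(g, float) for g in groups]
    k = len(arrays)
    if k < 2 or any(a.size < 2 for a in arrays):
        raise ValidationError("need >= 2 groups with >= 2 values each")
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    N = int(ns.sum())
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df = N - k
    mse = sse / df
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            if mse == 0:
                if diff != 0:
                    logger.warning(
                        "zero within-group variance with unequal means: p = 0 reported"
                    )
                    pij = 0.0
                else:
                    pij = 1.0
            elif k == 2:
                t = diff / np.sqrt(mse * (1 / ns[i] + 1 / ns[j]))
                pij = 2 * stats.t.sf(abs(t), df)
            else:
                q = abs(diff) / np.sqrt(mse / 2 * (1 / ns[i] + 1 / ns[j]))
                pij = float(stats.studentized_range.sf(q, k, df))
            p[i, j] = p[j, i] = min(1.0, max(0.0, pij))
    return p


# ---------------------------------------------------------------------------
# per-feature group tests


def _tested_values(table: FeatureTable, scale: str) -> FeatureTable:
    cleaned = impute_half_minimum(clean_nonpositive(table))
    if scale == "log2":
        return FeatureTable(
            list(cleaned.sample_ids), list(cleaned.feature_ids), np.log2(cleaned.values)
        )
    if scale == "concentration":
        return cleaned
    raise ValidationError(f"unknown scale {scale!r} (use 'log2' or 'concentration')")


def per_feature_group_test(
    table: FeatureTable,
    metadata: Sequence[SampleMetadata],
    scale: str = "log2",
) -> list[GroupTestResult]:
    """Patient-vs-control Tukey HSD per feature, sorted by p-value.

    ``scale`` selects the tested values: "log2" (variance-stabilized,
    default) or "concentration" (cleaned + imputed raw values).
    """
    tested = _tested_values(table, scale)
    by_id = {m.sample_id: m for m in metadata}
    groups_idx = {"patient": [], "control": []}
    for r, sid in enumerate(tested.sample_ids):
        if sid in by_id:
            groups_idx[by_id[sid].group].append(r)
    if not groups_idx["patient"] or not groups_idx["control"]:
        raise ValidationError("both patient and control groups must be non-empty")
    pat = tested.values[groups_idx["patient"], :]
    ctl = tested.values[groups_idx["control"], :]
    results = []
    for c, fid in enumerate(tested.feature_ids):
        p = float(tukey_hsd([pat[:, c], ctl[:, c]])[0, 1])
        results.append(
            GroupTestResult(fid, float(pat[:, c].mean()), float(ctl[:, c].mean()), p, p < ALPHA)
        )
    results.sort(key=lambda r: (r.p_value, r.feature_id))
    return results


# ---------------------------------------------------------------------------
# multiple-testing correction


def adjust_pvalues(p: Sequence[float], method: str) -> np.ndarray:
    """Adjust p-values: "bonferroni" (min(1, m*p)) or "bh" (step-up FDR).

    Output is in the input order; values are capped at 1.
    """
    p = np.asarray(p, float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValidationError("p-values must lie in [0,1]")
    if method not in ("bh", "bonferroni"):
        raise ValidationError(f"unknown correction method {method!r}")
    if p.size == 0:
        return p.copy()
    sm_method = "fdr_bh" if method == "bh" else "bonferroni"
    return multipletests(p, alpha=ALPHA, method=sm_method)[1]


# ---------------------------------------------------------------------------
# antipsychotic confounder scan


def confounder_scan(
    table: FeatureTable,
    metadata: Sequence[SampleMetadata],
    scale: str = "log2",
    stratum: str = "patients",
) -> list[ConfounderScanResult]:
    """Linear-model scan of each feature on the antipsychotic flag.

    By default the model is fitted within the patient group only (controls
    are unmedicated by design); ``stratum="all"`` uses every sample. The
    coefficient and its t-test p for a binary predictor coincide with a
    two-sample flagged-vs-unflagged t-test.
    """
    tested = _tested_values(table, scale)
    by_id = {m.sample_id: m for m in metadata}
    rows, flags = [], []
    for r, sid in enumerate(tested.sample_ids):
        m = by_id.get(sid)
        if m is None:
            continue
        if stratum == "patients" and m.group != "patient":
            continue
        rows.append(r)
        flags.append(float(m.antipsychotic_flag))
    flags_arr = np.asarray(flags)
    if flags_arr.size < 3 or len(np.unique(flags_arr)) < 2:
        raise ValidationError(
            "antipsychotic flag constant (or too few samples) within the scanned stratum"
        )
    X = sm.add_constant(flags_arr)
    coefs, praw = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c in range(tested.values.shape[1]):
            fit = sm.OLS(tested.values[rows, c], X).fit()
            coefs.append(float(fit.params[1]))
            praw.append(float(np.clip(fit.pvalues[1], 0.0, 1.0)))
    p_bh = adjust_pvalues(praw, "bh")
    p_bonf = adjust_pvalues(praw, "bonferroni")
    return [
        ConfounderScanResult(
            fid,
            coefs[i],
            praw[i],
            float(p_bh[i]),
            float(p_bonf[i]),
            bool(min(p_bh[i], p_bonf[i]) < ALPHA),
        )
        for i, fid in enumerate(tested.feature_ids)
    ]
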