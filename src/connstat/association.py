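"""Partial Spearman correlations between limbic features and symptom scores.

Computed within the patient group only.  Partial Spearman = rank both
variables (average ranks for ties), residualize both rank vectors on the
covariates by least squares, correlate the residuals; the p-value uses the
t approximation with df = n - n_covariates - 2.  FDR is applied separately
within the 8-test hippocampus family and the 12-test amygdala family.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from connstat.inference import _build_covariate_matrix, fdr_bh
from connstat.io import Cohort
from connstat.metrics import NodalFeatureTable

logger = logging.getLogger(__name__)

ASSOC_COVARIATE_DEFAULT = ("age", "sex", "volume", "medication")

SCORE_ATTR = {"MADRS": "madrs", "QIDS": "qids", "episode_duration": "episode_duration"}


def partial_spearman(x, y, covariates=None) -> tuple[float, float, int]:
    """Rank-based partial correlation of x and y given covariates.

    Returns (rho, p, n_used).  Invariant under strictly monotone transforms
    of x or y; with zero covariates it equals plain Spearman rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariate matrix does not match x/y length")
    ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    n_used = int(ok.sum())
    if n_used < 5:
        raise ValueError(f"need >= 5 complete cases, got {n_used}")
    xr = stats.rankdata(x[ok])
    yr = stats.rankdata(y[ok])
    if np.all(xr == xr[0]):
        raise ValueError("constant x after ranking")
    if np.all(yr == yr[0]):
        raise ValueError("constant y after ranking")
    X0 = np.column_stack([np.ones(n_used), C[ok]])
    Q, _ = np.linalg.qr(X0)
    rx = xr - Q @ (Q.T @ xr)
    ry = yr - Q @ (Q.T @ yr)
    nx, ny = np.linalg.norm(rx), np.linalg.norm(ry)
    if nx == 0 or ny == 0:
        raise ValueError("ranks fully explained by covariates")
    rho = float(np.clip((rx @ ry) / (nx * ny), -1.0, 1.0))
    df = n_used - C.shape[1] - 2
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p, n_used


def associate_limbic(
    features: NodalFeatureTable,
    cohort: Cohort,
    score_name: str = "MADRS",
    covariates=ASSOC_COVARIATE_DEFAULT,
    q: float = 0.05,
    corrected: bool = True,
) -> pd.DataFrame:
    """Partial Spearman association of each limbic subregion's features with
    a symptom score, in patients only, with per-family BH-FDR.

    Hippocampal subregions form an 8-test family and amygdala nuclei a
    12-test family, corrected separately per metric.  ``corrected=False``
    reports uncorrected p only (used for exploratory scores such as
    episode duration).
    """
    if score_name not in SCORE_ATTR:
        raise ValueError(f"unknown score {score_name!r}; expected one of {sorted(SCORE_ATTR)}")
    attr = SCORE_ATTR[score_name]
    patients = cohort.indices_of_group("MDD")
    if len(patients) == 0:
        raise ValueError("no MDD subjects in cohort")
    score = np.array(
        [np.nan if getattr(cohort.subjects[i], attr) is None else float(getattr(cohort.subjects[i], attr))
         for i in patients]
    )
    finite_scores = score[np.isfinite(score)]
    if finite_scores.size and np.all(finite_scores == finite_scores[0]):
        raise ValueError(f"constant y: score {score_name} has no variation among patients")
    sid_pos = {s: i for i, s in enumerate(features.subject_ids)}
    feat_rows = np.array([sid_pos[cohort.subjects[i].subject_id] for i in patients])
    rows = []
    for metric in features.metrics:
        arr = features.data[metric]
        for family in ("hippocampus", "amygdala"):
            fam_idx = cohort.region_table.family_indices(family)
            if len(fam_idx) == 0:
                continue
            fam_rows = []
            for r in fam_idx:
                C, mask = _build_covariate_matrix(cohort, covariates, int(r), patients)
                x = arr[feat_rows, r].astype(float)
                x = np.where(mask, x, np.nan)  # missing covariate -> listwise drop
                Cfull = np.where(mask[:, None], C, np.nan) if C.shape[1] else C
                rho, p, n_used = partial_spearman(x, score, Cfull)
                fam_rows.append(
                    {
                        "region_index": int(r),
                        "region": cohort.region_table.names[r],
                        "family": family,
                        "metric": metric,
                        "score": score_name,
                        "rho": rho,
                        "p": p,
                        "n_used": n_used,
                    }
                )
            if corrected:
                qv, _ = fdr_bh([row["p"] for row in fam_rows], q)
                for row, v in zip(fam_rows, qv):
                    row["q_fdr"] = float(v)
                    row["significant"] = bool(v <= q)
            else:
                for row in fam_rows:
                    row["uncorrected"] = True
            rows.extend(fam_rows)
    if not rows:
        raise ValueError("region table has no limbic subregions")
    return pd.DataFrame(rows)
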