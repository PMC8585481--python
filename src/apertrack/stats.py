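"""Inferential layer: residualization, attention contrasts, tracking
betas, permutation and cluster-permutation tests, multiplicity control
and behavioural preprocessing.

Conventions
-----------
* Attention is effect-coded +-0.5 (zero-centred), auditory negative.
* Permutation p-values are two-sided on |t| with the >= convention,
  p = #(|t_perm| >= |t_obs|) / n_perm; set ``include_observed`` for the
  (k+1)/(n+1) variant, and ``tails='greater'`` for the one-sided count.
* The 2x2 repeated-measures ANOVA is computed from sums of squares for
  the within-subject design; partial eta^2 = SS_effect / (SS_effect +
  SS_error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .synthexp import CENTRAL_ROI, OCCIPITAL_ROI

__all__ = [
    "StatResult",
    "TrackingBeta",
    "ClusterResult",
    "residualize",
    "attention_contrast",
    "tracking_beta",
    "permutation_contrast",
    "cluster_permutation",
    "multiplicity",
    "prep_behavior",
    "group_tracking_test",
]


@dataclass(frozen=True)
class StatResult:
    statistic: float
    df: object
    p: float
    effect_size: float | None = None
    effect_size_name: str | None = None
    tails: str = "two-sided"
    n_perm: int | None = None
    note: str | None = None


@dataclass(frozen=True)
class TrackingBeta:
    subject: object
    modality: str  # modality whose stimulus exponent is the step-2 predictor
    attention_subset: str  # "all" | "auditory" | "visual"
    beta: float
    electrode: str | None = None
    n_trials: int | None = None


@dataclass(frozen=True)
class ClusterResult:
    clusters: tuple  # tuples of member positions
    masses: np.ndarray  # summed t per cluster
    p: np.ndarray
    t_map: np.ndarray
    threshold: float
    n_perm: int


def _zscore(x):
    x = np.asarray(x, float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant variable")
    return (x - x.mean()) / sd


def residualize(y, X=None) -> np.ndarray:
    """Least-squares residuals of y on [1, X] (demeaning when X is empty)."""
    y = np.asarray(y, float)
    if X is None or (hasattr(X, "size") and np.asarray(X).size == 0) or \
            (hasattr(X, "__len__") and len(X) == 0):
        return y - y.mean()
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and X must have the same number of rows")
    A = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # identify offending columns via successive rank checks
        bad = []
        for j in range(1, A.shape[1]):
            if np.linalg.matrix_rank(A[:, : j + 1]) < j + 1:
                bad.append(j - 1)
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {bad}")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return y - A @ coef


def _paired_t(a, b):
    d = np.asarray(a, float) - np.asarray(b, float)
    t, p = spstats.ttest_rel(a, b)
    sd = d.std(ddof=1)
    cohen_d = d.mean() / sd if sd > 0 else np.inf * np.sign(d.mean() or 1)
    return StatResult(float(t), len(d) - 1, float(p), float(cohen_d), "cohen_d")


def _rm_anova_2x2(cells: np.ndarray):
    """Sums-of-squares 2x2 within-subject ANOVA.

    ``cells``: (n_subjects, 2, 2) array, factors (A, B).  Returns dict of
    StatResult for 'A', 'B' and 'AxB', each F with (1, n-1) df and partial
    eta squared.
    """
    n = cells.shape[0]
    out = {}
    # each effect reduces to a paired contrast; F = t^2 in the 2x2 case,
    # computed via its own SS decomposition
    contrasts = {
        "A": cells[:, 1, :].mean(axis=1) - cells[:, 0, :].mean(axis=1),
        "B": cells[:, :, 1].mean(axis=1) - cells[:, :, 0].mean(axis=1),
        "AxB": (cells[:, 1, 1] - cells[:, 1, 0]) - (cells[:, 0, 1] - cells[:, 0, 0]),
    }
    for name, c in contrasts.items():
        ss_effect = n * c.mean() ** 2
        ss_error = np.sum((c - c.mean()) ** 2) / 1.0
        ms_error = ss_error / (n - 1)
        if ms_error > 0:
            F = ss_effect / ms_error
        else:
            F = 0.0 if ss_effect == 0 else np.inf
        p = float(spstats.f.sf(F, 1, n - 1)) if np.isfinite(F) else 0.0
        pes = ss_effect / (ss_effect + ss_error) if (ss_effect + ss_error) > 0 else 0.0
        out[name] = StatResult(float(F), (1, n - 1), p, float(pes), "partial_eta_sq")
    return out


_COVARIATES = ("chi_aud", "chi_vis", "alpha", "trial")


def _residualized_condition_means(table: pd.DataFrame, electrodes):
    """Per subject: residualize each electrode's exponent on the trial-wise
    covariates (auditory/visual stimulus exponents, alpha power, trial
    number), then average residuals per attention condition."""
    recs = []
    for subj, sub in table.groupby("subject"):
        for el in electrodes:
            X = np.column_stack([
                sub["chi_aud"], sub["chi_vis"], sub[f"alpha_{el}"], sub["trial"],
            ])
            resid = residualize(sub[f"exp_{el}"].to_numpy(), X)
            for cond in ("auditory", "visual"):
                mask = (sub["attention"] == cond).to_numpy()
                if not mask.any():
                    continue
                recs.append({"subject": subj, "electrode": el,
                             "attention": cond, "resid": resid[mask].mean()})
    return pd.DataFrame(recs)


def attention_contrast(table: pd.DataFrame, central_roi=CENTRAL_ROI,
                       occipital_roi=OCCIPITAL_ROI, warn=None):
    """Attention x ROI contrast of residualized EEG spectral exponents.

    Exponents are residualized per subject and electrode on stimulus
    exponents, alpha power and trial number; residuals are averaged per
    electrode x attention condition, then per ROI; a 2x2 within-subject
    ANOVA (ROI x attention) with paired follow-ups per ROI completes the
    contrast.

    Returns (cell-means DataFrame, anova dict, follow-ups dict).
    """
    electrodes = tuple(central_roi) + tuple(occipital_roi)
    means = _residualized_condition_means(table, electrodes)
    means["roi"] = np.where(means["electrode"].isin(central_roi), "central", "occipital")
    cell = (means.groupby(["subject", "roi", "attention"])["resid"]
            .mean().reset_index())
    # keep only subjects with all four cells
    counts = cell.groupby("subject").size()
    complete = counts[counts == 4].index
    dropped = counts[counts != 4].index.tolist()
    if dropped and warn is not None:
        warn(f"excluded subjects missing a condition: {dropped}")
    cell = cell[cell["subject"].isin(complete)]
    wide = cell.pivot_table(index="subject", columns=["roi", "attention"],
                            values="resid")
    arr = np.stack([
        [wide[("central", "auditory")], wide[("central", "visual")]],
        [wide[("occipital", "auditory")], wide[("occipital", "visual")]],
    ], axis=0)  # (roi, attention, subject)
    cells = np.transpose(arr, (2, 0, 1))
    anova = _rm_anova_2x2(cells)
    anova = {"roi": anova["A"], "attention": anova["B"], "interaction": anova["AxB"]}
    followups = {
        "central": _paired_t(cells[:, 0, 0], cells[:, 0, 1]),
        "occipital": _paired_t(cells[:, 1, 0], cells[:, 1, 1]),
    }
    return cell, anova, followups


def tracking_beta(subject_trials: pd.DataFrame, target_modality: str,
                  attention_subset: str = "all",
                  eeg_col: str | None = None) -> TrackingBeta:
    """Two-step single-subject stimulus-tracking estimate.

    Step 1 regresses the EEG spectral exponent on attentional focus
    (effect-coded +-0.5), trial number and the *other* modality's stimulus
    exponent; step 2 regresses the z-scored step-1 residuals on the
    z-scored target-modality stimulus exponent.  The step-2 slope is the
    standardized tracking beta.
    """
    if target_modality not in ("auditory", "visual"):
        raise ValueError("target_modality must be 'auditory' or 'visual'")
    sub = subject_trials
    if attention_subset != "all":
        sub = sub[sub["attention"] == attention_subset]
    if len(sub) < 20:
        raise ValueError("fewer than 20 trials after subsetting")
    if eeg_col is None:
        exp_cols = [c for c in sub.columns if c.startswith("exp_")]
        eeg = sub[exp_cols].mean(axis=1).to_numpy()
    else:
        eeg = sub[eeg_col].to_numpy()
    target_col = "chi_aud" if target_modality == "auditory" else "chi_vis"
    other_col = "chi_vis" if target_modality == "auditory" else "chi_aud"
    if np.std(sub[target_col]) == 0:
        raise ValueError("target-modality stimulus exponent is constant")
    att = np.where(sub["attention"] == "visual", 0.5, -0.5)
    covs = [sub["trial"].to_numpy(), sub[other_col].to_numpy()]
    if attention_subset == "all":
        covs.insert(0, att)
    resid = residualize(eeg, np.column_stack(covs))
    z_resid = _zscore(resid)
    z_target = _zscore(sub[target_col].to_numpy())
    beta = float(np.linalg.lstsq(
        np.column_stack([np.ones_like(z_target), z_target]), z_resid, rcond=None)[0][1])
    subj = sub["subject"].iloc[0] if "subject" in sub else None
    return TrackingBeta(subj, target_modality, attention_subset, beta,
                        electrode=eeg_col, n_trials=len(sub))


def permutation_contrast(epochs_a, epochs_b, n_perm: int = 1000, seed: int = 0,
                         tails: str = "two-sided",
                         include_observed: bool = False, warn=None) -> StatResult:
    """Label-permutation paired contrast of epoch-wise values.

    ``epochs_a``/``epochs_b`` are lists (one entry per subject) of 1-D
    arrays of epoch values for the two conditions.  The observed statistic
    is a paired t on subject-wise condition means; the null shuffles
    epoch-level condition labels within subject.
    """
    if n_perm < 100 and warn is not None:
        warn(f"n_perm = {n_perm} is small; empirical p resolution is 1/{n_perm}")
    rng = np.random.default_rng(seed)
    a = [np.asarray(x, float) for x in epochs_a]
    b = [np.asarray(x, float) for x in epochs_b]
    if any(x.size < 2 or y.size < 2 for x, y in zip(a, b)):
        raise ValueError("each subject needs >= 2 epochs per condition")
    means_a = np.array([x.mean() for x in a])
    means_b = np.array([x.mean() for x in b])
    t_obs, _ = spstats.ttest_rel(means_a, means_b)
    pooled = [np.concatenate([x, y]) for x, y in zip(a, b)]
    n_a = [x.size for x in a]
    t_null = np.empty(n_perm)
    for k in range(n_perm):
        ma = np.empty(len(pooled))
        mb = np.empty(len(pooled))
        for s, pool in enumerate(pooled):
            perm = rng.permutation(pool)
            ma[s] = perm[: n_a[s]].mean()
            mb[s] = perm[n_a[s]:].mean()
        t_null[k], _ = spstats.ttest_rel(ma, mb)
    if tails == "two-sided":
        count = int(np.sum(np.abs(t_null) >= abs(t_obs)))
    elif tails == "greater":
        count = int(np.sum(t_null >= t_obs))
    else:
        raise ValueError("tails must be 'two-sided' or 'greater'")
    p = (count + include_observed) / (n_perm + include_observed)
    d = means_a - means_b
    cohen_d = d.mean() / d.std(ddof=1) if d.std(ddof=1) > 0 else np.inf
    return StatResult(float(t_obs), len(a) - 1, float(p), float(cohen_d),
                      "cohen_d", tails, n_perm)


def _clusters_from_mask(mask: np.ndarray, adjacency: np.ndarray):
    """Connected components of True positions under the adjacency matrix."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    idx_set = set(idx.tolist())
    seen: set = set()
    clusters = []
    for start in idx:
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        stack = [start]
        while stack:
            node = stack.pop()
            for nb in np.flatnonzero(adjacency[node]):
                if nb in idx_set and nb not in seen:
                    seen.add(nb)
                    comp.append(nb)
                    stack.append(nb)
        clusters.append(tuple(sorted(int(i) for i in comp)))
    return clusters


def _cluster_masses(t_map, thresh, adjacency):
    """Suprathreshold clusters and masses, positive and negative separately."""
    clusters, masses = [], []
    for sign in (1, -1):
        for cl in _clusters_from_mask(sign * t_map > thresh, adjacency):
            clusters.append(cl)
            masses.append(t_map[list(cl)].sum())
    return clusters, np.asarray(masses)


def cluster_permutation(values: np.ndarray, adjacency: np.ndarray,
                        t_threshold: float | None = None, n_perm: int = 1000,
                        seed: int = 0) -> ClusterResult:
    """Cluster-based sign-flip permutation test of subjects x positions data.

    Position-wise one-sample t against zero, thresholded at |t| >
    ``t_threshold`` (default: two-sided p < 0.05 critical t with
    n_subjects - 1 df); suprathreshold clusters connected under
    ``adjacency`` are scored by summed t; the null distribution is the
    maximum |cluster mass| under random sign flips of subjects.
    """
    X = np.asarray(values, float)
    n_sub, n_pos = X.shape
    adjacency = np.asarray(adjacency)
    if adjacency.shape != (n_pos, n_pos) or adjacency.size == 0:
        raise ValueError("adjacency must be a non-empty n_positions x n_positions matrix")
    if t_threshold is None:
        t_threshold = float(spstats.t.ppf(0.975, n_sub - 1))

    def tmap(data):
        m = data.mean(axis=0)
        se = data.std(axis=0, ddof=1) / np.sqrt(data.shape[0])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, m / se, 0.0)
        return t

    t_obs = tmap(X)
    clusters, masses = _cluster_masses(t_obs, t_threshold, adjacency)
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    for k in range(n_perm):
        t_p = tmap(X * signs[k][:, None])
        _, m = _cluster_masses(t_p, t_threshold, adjacency)
        null_max[k] = np.max(np.abs(m)) if m.size else 0.0
    p = np.array([np.mean(null_max >= abs(m)) for m in masses]) if masses.size \
        else np.empty(0)
    return ClusterResult(tuple(clusters), masses, p, t_obs,
                         float(t_threshold), n_perm)


def multiplicity(p_values, method: str = "holm", alpha: float = 0.05):
    """Multiple-comparison decisions: Bonferroni-Holm or Benjamini-Hochberg.

    Returns (reject mask, adjusted p-values).
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"holm": "holm", "bh_fdr": "fdr_bh"}[method]
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method=sm_method)
    return reject, p_adj


def prep_behavior(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject behavioural features for the brain-behaviour analysis.

    Accuracy per modality is residualized across subjects on the final
    staircase modulation depth of that modality; response speed (1/RT) is
    residualized on trial number within subject and averaged.  Returns one
    row per subject with columns acc_aud, acc_vis, speed_aud, speed_vis.
    """
    rows = []
    for subj, sub in table.groupby("subject"):
        rec = {"subject": subj}
        for mod in ("auditory", "visual"):
            short = "aud" if mod == "auditory" else "vis"
            cond = sub[sub["attention"] == mod]
            if cond.empty:
                raise ValueError(f"subject {subj} has no {mod} trials")
            rec[f"acc_{short}"] = cond["correct"].mean()
            rec[f"depth_{short}"] = cond["depth"].iloc[-1]
            resp = cond.dropna(subset=["rt_s"])
            if (resp["rt_s"] <= 0).any():
                raise ValueError("non-positive reaction time")
            speed = 1.0 / resp["rt_s"].to_numpy()
            rec[f"speed_{short}"] = residualize(speed, resp["trial"].to_numpy()).mean()
        rows.append(rec)
    df = pd.DataFrame(rows).set_index("subject")
    for short in ("aud", "vis"):
        df[f"acc_{short}"] = residualize(df[f"acc_{short}"].to_numpy(),
                                         df[f"depth_{short}"].to_numpy())
    return df[["acc_aud", "acc_vis", "speed_aud", "speed_vis"]]


def group_tracking_test(betas) -> StatResult:
    """One-sample t of subject-wise tracking betas against zero."""
    b = np.asarray([x.beta if isinstance(x, TrackingBeta) else x for x in betas], float)
    if b.size < 3:
        raise ValueError("need at least 3 subjects")
    sd = b.std(ddof=1)
    if sd == 0:
        return StatResult(np.inf if b.mean() != 0 else 0.0, b.size - 1,
                          0.0 if b.mean() != 0 else 1.0, None, "cohen_d",
                          note="degenerate: zero between-subject variance")
    t, p = spstats.ttest_1samp(b, 0.0)
    return StatResult(float(t), b.size - 1, float(p), float(b.mean() / sd), "cohen_d")
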