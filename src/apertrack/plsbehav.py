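"""Behavioural partial least squares (PLS) on brain-behaviour rank correlations.

Behavioural PLS starts from the between-subject Spearman correlation
matrix R linking every brain feature (here: electrode-wise stimulus
tracking betas, one set per modality) with every behavioural measure.
R is decomposed by singular value decomposition, R = U S V'; each latent
variable (LV) pairs a brain salience pattern (column of U) with a
behaviour weight profile (column of V), and its singular value measures
the cross-block covariance it accounts for.  Significance is assessed by
permuting behaviour rows across subjects; the robustness of saliences by
bootstrap resampling of subjects, summarized as bootstrap ratios
(salience / bootstrap SE, a pseudo-Z) and percentile confidence
intervals for the behaviour-level correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

__all__ = ["PLSInput", "PLSResult", "corr_matrix", "pls_svd",
           "pls_permutation", "pls_bootstrap", "run_pls"]


@dataclass(frozen=True)
class PLSInput:
    """Brain (subjects x features) and behaviour (subjects x measures) blocks."""

    brain: np.ndarray
    behavior: np.ndarray
    brain_names: tuple = ()
    behavior_names: tuple = ()
    method: str = "spearman"

    def __post_init__(self):
        brain = np.atleast_2d(np.asarray(self.brain, float))
        behav = np.atleast_2d(np.asarray(self.behavior, float))
        if brain.shape[0] != behav.shape[0]:
            raise ValueError("brain and behaviour must have equal subject counts")
        if np.isnan(brain).any() or np.isnan(behav).any():
            raise ValueError("missing values are not allowed")
        if self.method != "spearman":
            raise ValueError("only spearman correlation is supported")
        object.__setattr__(self, "brain", brain)
        object.__setattr__(self, "behavior", behav)


@dataclass(frozen=True)
class PLSResult:
    singular_values: np.ndarray
    brain_saliences: np.ndarray  # (n_brain_features, n_lv)
    behavior_weights: np.ndarray  # (n_behaviors, n_lv)
    brain_scores: np.ndarray  # (n_subjects, n_lv)
    perm_p: np.ndarray | None = None
    bootstrap_ratios: np.ndarray | None = None
    behavior_cis: np.ndarray | None = None  # (n_brain, n_behav, 2) or (n_behav, n_lv, 2)
    n_perm: int | None = None
    n_boot: int | None = None


def _rankdata_cols(M: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(spstats.rankdata, 0, M)


def corr_matrix(inp: PLSInput) -> np.ndarray:
    """Spearman correlation of every brain feature with every behaviour.

    Returns an (n_brain_features x n_behaviors) matrix.
    """
    if inp.brain.shape[0] < 4:
        raise ValueError("need at least 4 subjects")
    for name, block in (("brain", inp.brain), ("behavior", inp.behavior)):
        sd = block.std(axis=0)
        if np.any(sd == 0):
            idx = np.flatnonzero(sd == 0)
            names = inp.brain_names if name == "brain" else inp.behavior_names
            labels = [names[i] if i < len(names) else str(i) for i in idx]
            raise ValueError(f"zero-variance {name} feature(s): {labels}")
    rb = _rankdata_cols(inp.brain)
    rv = _rankdata_cols(inp.behavior)
    rb = (rb - rb.mean(axis=0)) / rb.std(axis=0)
    rv = (rv - rv.mean(axis=0)) / rv.std(axis=0)
    return rb.T @ rv / rb.shape[0]


def pls_svd(R: np.ndarray, brain: np.ndarray | None = None) -> PLSResult:
    """SVD of the correlation matrix; LVs ordered by singular value.

    Brain scores are the projection of the (z-scored rank) brain block on
    the brain saliences when ``brain`` is given.
    """
    R = np.asarray(R, float)
    if not np.all(np.isfinite(R)):
        raise ValueError("correlation matrix must be finite")
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    scores = np.empty((0, s.size))
    if brain is not None:
        rb = _rankdata_cols(np.atleast_2d(np.asarray(brain, float)))
        rb = (rb - rb.mean(axis=0)) / rb.std(axis=0)
        scores = rb @ U
    return PLSResult(s, U, Vt.T, scores)


def pls_permutation(inp: PLSInput, n_perm: int = 5000, seed: int = 0) -> np.ndarray:
    """Permutation p per LV: behaviour rows shuffled across subjects.

    Each observed singular value is compared with the null distribution of
    the same-ranked singular value (p with the >= convention).
    """
    R = corr_matrix(inp)
    s_obs = np.linalg.svd(R, compute_uv=False)
    rng = np.random.default_rng(seed)
    n = inp.behavior.shape[0]
    # ranks are permutation-equivariant: rank once, permute behaviour rows
    rb = _rankdata_cols(inp.brain)
    rv = _rankdata_cols(inp.behavior)
    rb = (rb - rb.mean(axis=0)) / rb.std(axis=0)
    rv = (rv - rv.mean(axis=0)) / rv.std(axis=0)
    count = np.zeros(s_obs.size)
    for _ in range(n_perm):
        Rp = rb.T @ rv[rng.permutation(n)] / n
        sp = np.linalg.svd(Rp, compute_uv=False)
        count += sp >= s_obs
    return count / n_perm


def _align(U, s, Vt, U_ref):
    """Match bootstrap singular vectors to the reference by maximal |inner
    product| (order), then flip signs to agree (Procrustes-lite)."""
    k = U_ref.shape[1]
    corr = np.abs(U_ref.T @ U)  # (k_ref, k_boot)
    order = []
    used = set()
    for i in range(k):
        for j in np.argsort(corr[i])[::-1]:
            if j not in used:
                order.append(j)
                used.add(j)
                break
    U2, s2, V2 = U[:, order], s[list(order)], Vt.T[:, order]
    signs = np.sign(np.sum(U_ref * U2, axis=0))
    signs[signs == 0] = 1
    return U2 * signs, s2, V2 * signs


def pls_bootstrap(inp: PLSInput, n_boot: int = 5000, seed: int = 0,
                  max_redraws: int = 100, log=None):
    """Bootstrap ratios and 95 % CIs by subject resampling with replacement.

    Each resample recomputes the correlation matrix and its SVD; solutions
    are sign/order aligned to the original before accumulation.  BSR =
    original salience / bootstrap SE of the salience.  Percentile CIs are
    returned for the behaviour-level correlations (each behaviour's
    correlation with the LV brain score pattern via its weight), i.e. for
    the entries of V scaled by the singular values.

    Returns (bootstrap_ratios (n_brain x n_lv), behavior_cis (n_behav x n_lv x 2)).
    """
    R = corr_matrix(inp)
    base = pls_svd(R, inp.brain)
    k = base.singular_values.size
    rng = np.random.default_rng(seed)
    n = inp.brain.shape[0]
    boot_U = np.empty((n_boot, R.shape[0], k))
    boot_sv = np.empty((n_boot, inp.behavior.shape[1], k))
    redraws = 0
    for b in range(n_boot):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, n)
            try:
                Rb = corr_matrix(PLSInput(inp.brain[idx], inp.behavior[idx]))
                break
            except ValueError:
                redraws += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        Ub, sb, Vtb = np.linalg.svd(Rb, full_matrices=False)
        U2, s2, V2 = _align(Ub, sb, Vtb, base.brain_saliences)
        boot_U[b] = U2
        boot_sv[b] = V2 * s2  # behaviour weights scaled by covariance strength
    if redraws and log is not None:
        log(f"pls_bootstrap: {redraws} degenerate resamples redrawn")
    se = boot_U.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(se > 0, base.brain_saliences / se, np.inf)
    cis = np.stack([np.percentile(boot_sv, 2.5, axis=0),
                    np.percentile(boot_sv, 97.5, axis=0)], axis=-1)
    return bsr, cis


def run_pls(inp: PLSInput, n_perm: int = 5000, n_boot: int = 5000,
            seed: int = 0) -> PLSResult:
    """Full behavioural PLS: SVD + permutation p + bootstrap ratios/CIs."""
    R = corr_matrix(inp)
    base = pls_svd(R, inp.brain)
    p = pls_permutation(inp, n_perm, seed=seed)
    bsr, cis = pls_bootstrap(inp, n_boot, seed=seed + 1)
    return PLSResult(base.singular_values, base.brain_saliences,
                     base.behavior_weights, base.brain_scores,
                     perm_p=p, bootstrap_ratios=bsr, behavior_cis=cis,
                     n_perm=n_perm, n_boot=n_boot)


def run_pls_per_brain_var(inp: PLSInput, groups: dict, n_perm: int = 5000,
                          n_boot: int = 5000, seed: int = 0) -> dict:
    """Separate PLS per brain-variable group (e.g. one SVD per modality).

    ``groups`` maps a name to the column indices of that brain variable.
    An alternative to the single stacked SVD when the brain block holds
    several variable sets per electrode.
    """
    out = {}
    for i, (name, cols) in enumerate(groups.items()):
        sub = PLSInput(inp.brain[:, list(cols)], inp.behavior,
                       tuple(inp.brain_names[c] for c in cols) if inp.brain_names else (),
                       inp.behavior_names)
        out[name] = run_pls(sub, n_perm=n_perm, n_boot=n_boot, seed=seed + i)
    return out
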