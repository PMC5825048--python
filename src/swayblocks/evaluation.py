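"""Monte-Carlo cross-validated faller/non-faller discrimination.

The protocol, repeated ``n_reps`` times with fresh random 70/30 stratified
subject-level splits:

1. split subjects into train/test, preserving the faller proportion;
2. per condition, cut every statokinesigram into overlapping blocks and
   compute the raw 3-index descriptors;
3. fit the z-normalizer on the pooled TRAIN blocks of the condition and apply
   it to train and test blocks (no test leakage);
4. fit the 2-component mixture on the normalized train blocks and designate
   the UB component from the mean of the faller-derived train descriptors;
5. score the test blocks, average into trajectory and global subject scores,
   and measure faller/non-faller separation by ROC/AUC (faller = positive
   class, higher score = more faller-like).

The block length ``"full"`` treats the whole trimmed signal as a single
block — the classical global-indices baseline.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sp_stats

from .blocks_features import (
    describe_blocks,
    descriptors_to_array,
    fit_normalizer_array,
    normalize_array,
    split_blocks,
    whole_signal_block,
)
from .cop_data import Cohort, Condition, Label
from .exceptions import EvaluationError, InsufficientDataError
from .gmm_em import fit_gmm, label_ub_cluster
from .scoring import block_scores, global_score, trajectory_score, ub_fraction

BlockLength = Union[float, int, str]

FULL_SIGNAL = "full"
DEFAULT_TRAIN_FRAC = 0.7
DEFAULT_N_REPS = 30
DEFAULT_FPR_GRID_SIZE = 101

CONDITIONS = (Condition.EO, Condition.EC)


# ---------------------------------------------------------------------------
# Splitting and ROC
# ---------------------------------------------------------------------------

def stratified_split(
    cohort: Cohort,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    seed: Optional[int] = None,
) -> Tuple[List[str], List[str]]:
    """Subject-level stratified train/test split.

    Per class, ``round(train_frac * class size)`` subjects (half rounded up)
    go to the train set; both conditions of a subject stay together.
    """
    if not 0 < train_frac < 1:
        raise EvaluationError("train_frac must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_ids: List[str] = []
    test_ids: List[str] = []
    for label in (Label.NON_FALLER, Label.FALLER):
        ids = cohort.ids_by_label(label)
        if len(ids) < 2:
            raise EvaluationError(
                f"class {label.value!r} has {len(ids)} subject(s); "
                "need at least 2 for a stratified split"
            )
        n_train = int(np.floor(train_frac * len(ids) + 0.5))
        if n_train == 0 or n_train == len(ids):
            raise EvaluationError(
                f"train_frac {train_frac} leaves an empty train or test set "
                f"for class {label.value!r}"
            )
        perm = rng.permutation(len(ids))
        train_ids.extend(ids[i] for i in perm[:n_train])
        test_ids.extend(ids[i] for i in perm[n_train:])
    return train_ids, test_ids


def roc_auc(
    scores: Sequence[float], labels: Sequence[Label]
) -> Tuple[float, np.ndarray]:
    """ROC curve and trapezoidal AUC with faller as the positive class.

    Thresholds sweep the unique score values; tied scores enter the curve as
    a single diagonal segment, so the trapezoidal area equals the
    Mann-Whitney U statistic (ties counted 1/2) divided by n+ * n-.
    Returns ``(auc, points)`` with ``points`` an (m, 2) array of (FPR, TPR)
    starting at (0, 0) and ending at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.array([Label(l) is Label.FALLER for l in labels], dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC needs both classes present")
    order = np.argsort(-scores, kind="mergesort")
    y_sorted = y[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # keep the last index of each group of tied scores
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


# ---------------------------------------------------------------------------
# Descriptor cache
# ---------------------------------------------------------------------------

def _trajectory_descriptors(
    traj, block_length_s: BlockLength, overlap: float
) -> np.ndarray:
    """Raw (n_blocks, 3) descriptor matrix for one statokinesigram."""
    if block_length_s == FULL_SIGNAL:
        blocks = [whole_signal_block(traj)]
    else:
        blocks = split_blocks(traj, float(block_length_s), overlap)
    return descriptors_to_array(describe_blocks(blocks))


def compute_descriptor_cache(
    cohort: Cohort, block_length_s: BlockLength, overlap: float
) -> Dict[Tuple[str, Condition], np.ndarray]:
    """Raw descriptors per (subject, condition); split-independent, so they
    can be shared across MCCV repetitions."""
    cache: Dict[Tuple[str, Condition], np.ndarray] = {}
    for subject in cohort:
        for cond in CONDITIONS:
            traj = subject.get(cond)
            if traj is not None:
                cache[(subject.subject_id, cond)] = _trajectory_descriptors(
                    traj, block_length_s, overlap
                )
    return cache


def _sub_seed(seed: int, k: int) -> int:
    """Deterministic child seed below 2**31."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# One repetition
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RepetitionResult:
    """Outcome of a single train/test repetition."""

    auc: float
    roc_points: np.ndarray
    test_scores: Dict[str, float]
    ub_fraction_by_class: Dict[Label, float]
    converged: bool


def run_single_repetition(
    cohort: Cohort,
    block_length_s: BlockLength,
    overlap: float = 0.5,
    seed: int = 0,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    n_init: int = 20,
    cache: Optional[Dict[Tuple[str, Condition], np.ndarray]] = None,
) -> RepetitionResult:
    """Execute the full protocol for one stratified split.

    ``cohort`` must contain preprocessed statokinesigrams.  ``cache`` may hold
    precomputed raw descriptors (from :func:`compute_descriptor_cache`).
    """
    if cache is None:
        cache = compute_descriptor_cache(cohort, block_length_s, overlap)
    train_ids, test_ids = stratified_split(cohort, train_frac, seed=_sub_seed(seed, 0))
    train_set = set(train_ids)
    labels = {s.subject_id: s.label for s in cohort}

    test_cond_scores: Dict[str, Dict[Condition, np.ndarray]] = {
        sid: {} for sid in test_ids
    }
    converged = True
    for k, cond in enumerate(CONDITIONS):
        train_blocks = [
            cache[(sid, cond)] for sid in train_ids if (sid, cond) in cache
        ]
        if not train_blocks:
            continue
        train_Z = np.vstack(train_blocks)
        if train_Z.shape[0] < 10:
            raise InsufficientDataError(
                f"only {train_Z.shape[0]} training blocks for {cond.value}"
            )
        norm = fit_normalizer_array(train_Z)
        faller_Z = np.vstack(
            [np.empty((0, 3))]
            + [
                cache[(sid, cond)]
                for sid in train_ids
                if labels[sid] is Label.FALLER and (sid, cond) in cache
            ]
        )
        model = fit_gmm(
            normalize_array(norm, train_Z),
            n_init=n_init,
            seed=_sub_seed(seed, 1 + k),
            condition=cond,
        )
        converged = converged and model.converged
        model = label_ub_cluster(model, normalize_array(norm, faller_Z))
        for sid in test_ids:
            if (sid, cond) not in cache:
                continue
            z = normalize_array(norm, cache[(sid, cond)])
            test_cond_scores[sid][cond] = block_scores(model, z)

    test_scores: Dict[str, float] = {}
    ub_by_class: Dict[Label, List[float]] = {Label.FALLER: [], Label.NON_FALLER: []}
    for sid in test_ids:
        per_cond = test_cond_scores[sid]
        traj_scores = {c: trajectory_score(s) for c, s in per_cond.items()}
        test_scores[sid] = global_score(
            traj_scores.get(Condition.EO), traj_scores.get(Condition.EC)
        )
        if Condition.EC in per_cond:
            ub_by_class[labels[sid]].append(ub_fraction(per_cond[Condition.EC]))

    auc, roc_points = roc_auc(
        [test_scores[sid] for sid in test_ids], [labels[sid] for sid in test_ids]
    )
    ub_fraction_by_class = {
        lab: float(np.mean(vals)) if vals else float("nan")
        for lab, vals in ub_by_class.items()
    }
    return RepetitionResult(
        auc=auc,
        roc_points=roc_points,
        test_scores=test_scores,
        ub_fraction_by_class=ub_fraction_by_class,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EvalResult:
    """Aggregated MCCV outcome for one block length."""

    block_length: str
    aucs: np.ndarray
    mean_auc: float
    sd_auc: float
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    ub_fractions_faller: np.ndarray
    ub_fractions_nonfaller: np.ndarray
    n_not_converged: int

    def to_dict(self) -> dict:
        return {
            "block_length": self.block_length,
            "aucs": self.aucs.tolist(),
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "fpr_grid": self.fpr_grid.tolist(),
            "mean_tpr": self.mean_tpr.tolist(),
            "ub_fractions_faller": self.ub_fractions_faller.tolist(),
            "ub_fractions_nonfaller": self.ub_fractions_nonfaller.tolist(),
            "n_not_converged": self.n_not_converged,
        }


def run_mccv(
    cohort: Cohort,
    block_length_s: BlockLength,
    overlap: float = 0.5,
    n_reps: int = DEFAULT_N_REPS,
    base_seed: int = 0,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    n_init: int = 20,
) -> EvalResult:
    """Repeat the protocol ``n_reps`` times with seeds ``base_seed + r``.

    Everything (normalizer, mixture) is retrained from scratch per repetition.
    ROC curves are averaged vertically on a fixed 101-point FPR grid.
    """
    if n_reps < 2:
        raise EvaluationError("MCCV needs at least 2 repetitions")
    cache = compute_descriptor_cache(cohort, block_length_s, overlap)
    grid = np.linspace(0.0, 1.0, DEFAULT_FPR_GRID_SIZE)
    aucs, tprs, ub_f, ub_n = [], [], [], []
    n_not_converged = 0
    for r in range(n_reps):
        rep = run_single_repetition(
            cohort,
            block_length_s,
            overlap=overlap,
            seed=base_seed + r,
            train_frac=train_frac,
            n_init=n_init,
            cache=cache,
        )
        aucs.append(rep.auc)
        tprs.append(np.interp(grid, rep.roc_points[:, 0], rep.roc_points[:, 1]))
        ub_f.append(rep.ub_fraction_by_class[Label.FALLER])
        ub_n.append(rep.ub_fraction_by_class[Label.NON_FALLER])
        if not rep.converged:
            n_not_converged += 1
    aucs = np.array(aucs)
    return EvalResult(
        block_length=str(block_length_s),
        aucs=aucs,
        mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std(ddof=1)),
        fpr_grid=grid,
        mean_tpr=np.mean(tprs, axis=0),
        ub_fractions_faller=np.array(ub_f),
        ub_fractions_nonfaller=np.array(ub_n),
        n_not_converged=n_not_converged,
    )


def compare_eval_results(a: EvalResult, b: EvalResult) -> float:
    """Two-sided rank-sum (Mann-Whitney/Wilcoxon) p-value on the AUC samples.

    Exact null distribution for combined n <= 20 without ties, normal
    approximation with tie correction otherwise.
    """
    x, y = np.asarray(a.aucs, float), np.asarray(b.aucs, float)
    if len(x) < 2 or len(y) < 2:
        raise EvaluationError("need at least 2 repetitions per result")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = sp_stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)
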