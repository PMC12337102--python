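"""End-to-end scoring: event matching, TPR/FPR, pseudo-blocks, CV, statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .session import DetectedEvent, TrueEvent

DEFAULT_MATCH_TOLERANCE_S = 0.5


@dataclass
class MatchResult:
    """Assignment of detections to true attempts within a time tolerance."""

    attempt_matches: dict[int, list[int]]  # attempt index -> detection indices
    detection_status: list[str]  # per detection: "TP" | "duplicate-TP" | "FP"
    tolerance_s: float
    n_attempts: int

    @property
    def n_matched_attempts(self) -> int:
        return sum(1 for v in self.attempt_matches.values() if v)

    @property
    def n_fp(self) -> int:
        return self.detection_status.count("FP")


@dataclass
class EvalReport:
    tpr: float
    fpr: float
    n_attempts: int
    n_detections: int
    n_tp: int
    n_fp: int
    n_duplicates: int


def match_events(
    true_attempts: list[TrueEvent],
    detections: list[DetectedEvent],
    tolerance_s: float = DEFAULT_MATCH_TOLERANCE_S,
) -> MatchResult:
    """Assign each detection to the nearest attempt within the tolerance.

    Onset-to-onset distance.  Every detection within the tolerance of an
    attempt is assigned to it (ties go to the earlier attempt); the first
    (earliest) detection per attempt is the TP, further ones duplicate-TPs.
    Unassigned detections are FPs.
    """
    if tolerance_s < 0:
        raise ValueError("tolerance must be non-negative")
    onsets = np.array([t.onset_s for t in true_attempts])
    matches: dict[int, list[int]] = {i: [] for i in range(len(true_attempts))}
    status = ["FP"] * len(detections)
    order = sorted(range(len(detections)), key=lambda j: detections[j].onset_s)
    for j in order:
        d = detections[j].onset_s
        if onsets.size == 0:
            continue
        dist = np.abs(onsets - d)
        i = int(np.argmin(dist))  # argmin takes the first (earlier attempt) on ties
        if dist[i] <= tolerance_s + 1e-12:
            status[j] = "duplicate-TP" if matches[i] else "TP"
            matches[i].append(j)
    return MatchResult(
        attempt_matches=matches,
        detection_status=status,
        tolerance_s=tolerance_s,
        n_attempts=len(true_attempts),
    )


def compute_rates(match: MatchResult) -> EvalReport:
    """TPR = matched attempts / attempts; FPR = FP / (FP + once-counted TP)."""
    n_tp = match.n_matched_attempts
    n_fp = match.n_fp
    n_dup = match.detection_status.count("duplicate-TP")
    tpr = n_tp / match.n_attempts if match.n_attempts else 0.0
    denom = n_fp + n_tp  # duplicates counted once
    fpr = n_fp / denom if denom else 0.0
    return EvalReport(
        tpr=tpr, fpr=fpr,
        n_attempts=match.n_attempts,
        n_detections=len(match.detection_status),
        n_tp=n_tp, n_fp=n_fp, n_duplicates=n_dup,
    )


def pseudo_blocks(trial_outcomes: np.ndarray, k: int = 6, metric=np.mean) -> list[float]:
    """Metric over k consecutive trial groups (sizes differing by <= 1)."""
    outcomes = np.asarray(trial_outcomes, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(outcomes):
        raise ValueError("more pseudo-blocks than trials")
    return [float(metric(b)) for b in np.array_split(outcomes, k)]


def crossval(
    windows: np.ndarray,
    labels: np.ndarray,
    folds: int = 10,
    members_per_fold: int = 5,
    hyper=None,
    electrode_mask: np.ndarray | None = None,
    seed: int = 0,
    val_fraction: float = 0.1,
) -> np.ndarray:
    """Stratified k-fold CV with per-fold ensembles and early stopping.

    In each fold 90% of the data trains ``members_per_fold`` randomly
    initialized models (10% of that reserved as a validation set for early
    stopping) and the held-out 10% is scored by the ensemble mean.
    Returns the per-fold accuracies.
    """
    from sklearn.model_selection import StratifiedKFold, train_test_split

    from .classify import ClassifierHyper, apply_electrode_mask, fit_classifier

    if folds < 2:
        raise ValueError("need at least 2 folds")
    hyper = hyper or ClassifierHyper()
    y = np.asarray(labels, dtype=np.int64)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for f, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        tr_idx, val_idx = train_test_split(
            train_idx, test_size=val_fraction, random_state=seed + f,
            stratify=None,
        )
        fold_hyper = ClassifierHyper(**{**hyper.__dict__, "n_members": members_per_fold,
                                        "seed": hyper.seed * 100 + f})
        ens = fit_classifier(
            windows[tr_idx], y[tr_idx], hyper=fold_hyper,
            electrode_mask=electrode_mask,
            validation=(windows[val_idx], y[val_idx]),
        )
        X_test = apply_electrode_mask(windows[test_idx], electrode_mask)
        pred = np.argmax(ens.probabilities(X_test), axis=1)
        accs.append(float(np.mean(pred == y[test_idx])))
    return np.asarray(accs)


def fisher_compare(a_success: int, a_total: int, b_success: int, b_total: int) -> float:
    """Two-sided Fisher exact test p-value for two proportions."""
    for v in (a_success, a_total, b_success, b_total):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if a_success > a_total or b_success > b_total:
        raise ValueError("successes exceed totals")
    table = [[a_success, a_total - a_success], [b_success, b_total - b_success]]
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def holm_bonferroni(p_values) -> np.ndarray:
    """Step-down Holm adjustment with monotonicity enforcement, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min((m - rank) * p[idx], 1.0)
        running = max(running, val)
        adj[idx] = running
    return adj


def correlation_permutation(
    x, y, method: str = "spearman", n_perm: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Correlation with permutation p-value (two-sided, add-one corrected)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    if method == "spearman":
        corr = lambda a, b: stats.spearmanr(a, b).statistic
    elif method == "pearson":
        corr = lambda a, b: stats.pearsonr(a, b).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    r = float(corr(x, y))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r_perm = corr(x, rng.permutation(y))
        if abs(r_perm) >= abs(r) - 1e-15:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r, float(p)
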