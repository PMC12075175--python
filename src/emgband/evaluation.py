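"""Cross-validated accuracy, confusion matrices, and nonparametric statistics.

Decoders are compared per subject across electrode densities (medium = all
21 channels, low = the 7 middle channels) with paired nonparametric tests:
Wilcoxon signed-rank for two paired conditions, the Friedman test across
three decoders (df = 2), and Nemenyi rank-based post-hoc pairwise
comparisons gated on Friedman significance.  Splits are trial-wise: all
windows of one trial repetition stay in one fold, so no window-level
leakage inflates accuracy.
"""

from __future__ import annotations


import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedGroupKFold

from .features import WindowedFeatures
from .models import StcnConfig, TrainConfig, build_stcn, build_vanilla_tcn, fit_lda, train
from .recording import ConfigError


def _fit_decoder(kind: str, tensor, labels, model_cfg: StcnConfig | None,
                 train_cfg: TrainConfig | None, seed: int):
    model_cfg = model_cfg or StcnConfig()
    train_cfg = train_cfg or TrainConfig()
    if kind == "lda":
        return fit_lda(tensor, labels)
    classes = tuple(np.unique(labels))
    cfg = StcnConfig(**{**model_cfg.__dict__, "classes": classes})
    tcfg = TrainConfig(**{**train_cfg.__dict__, "seed": seed})
    shape = tensor.shape[1:]
    if kind == "stcn":
        net = build_stcn(cfg, shape, seed=seed)
    elif kind == "tcn":
        net = build_vanilla_tcn(cfg, shape, seed=seed)
    else:
        raise ConfigError(f"unknown decoder kind '{kind}'")
    return train(net, tensor, labels, tcfg, kind=kind)


def cross_validate(feats: WindowedFeatures, decoder_kind: str, n_splits: int = 5,
                   model_cfg: StcnConfig | None = None,
                   train_cfg: TrainConfig | None = None, seed: int = 0,
                   return_predictions: bool = False):
    """Trial-wise stratified k-fold accuracy for one subject's session.

    Folds are formed over trial repetitions (``feats.groups``), never over
    individual model samples, so all windows of a trial land in one fold.
    Returns the mean accuracy over folds (and optionally the pooled
    out-of-fold predictions and labels).
    """
    tensor, labels, groups = feats.tensor, feats.labels, feats.groups
    _, trial_counts = np.unique(labels[np.unique(groups, return_index=True)[1]],
                                return_counts=True)
    if n_splits > trial_counts.min():
        raise ConfigError(
            f"n_splits={n_splits} exceeds the {trial_counts.min()} trials of the rarest class"
        )
    cv = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    accs, all_preds, all_true = [], [], []
    for fold, (tr, te) in enumerate(cv.split(tensor, labels, groups)):
        dec = _fit_decoder(decoder_kind, tensor[tr], labels[tr], model_cfg, train_cfg,
                           seed=seed * 1009 + fold)
        preds = dec.predict(tensor[te])
        accs.append(float(np.mean(preds == labels[te])))
        all_preds.append(preds)
        all_true.append(labels[te])
    if return_predictions:
        return float(np.mean(accs)), np.concatenate(all_preds), np.concatenate(all_true)
    return float(np.mean(accs))


def confusion(preds: np.ndarray, labels: np.ndarray, classes: np.ndarray) -> dict:
    """Count and row-normalized confusion matrices over the given class list."""
    preds, labels = np.asarray(preds), np.asarray(labels)
    if preds.shape != labels.shape:
        raise ConfigError("preds and labels must have equal length")
    unknown = set(np.unique(np.concatenate([preds, labels]))) - set(np.asarray(classes).tolist())
    if unknown:
        raise ConfigError(f"unknown class ids {sorted(unknown)}")
    counts = confusion_matrix(labels, preds, labels=classes)
    row_sums = counts.sum(axis=1, keepdims=True)
    normalized = np.divide(counts, row_sums, out=np.zeros_like(counts, dtype=float),
                           where=row_sums > 0)
    return {"counts": counts, "normalized": normalized, "classes": np.asarray(classes)}


# ------------------------------------------------------------- statistics

def wilcoxon_exact(x: np.ndarray, y: np.ndarray | None = None,
                   alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples (or precomputed diffs).

    Zero differences are dropped (classical Wilcoxon convention).  The
    exact null distribution is used for n <= 12 pairs without ties; the
    normal approximation with continuity correction above.  Identical
    pairs everywhere give W = 0, p = 1.
    """
    d = np.asarray(x, dtype=float) if y is None else np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    mode = "exact" if d.size <= 12 else "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=mode, correction=(mode == "approx"))
    return float(res.statistic), float(res.pvalue)


def friedman_test(table: np.ndarray) -> tuple[float, int, float]:
    """Friedman chi-square across the columns of a subjects x conditions table.

    Uses average within-row ranks with the standard tie correction; a table
    whose rows are all completely tied yields chi2 = 0, p = 1 (df = k - 1).
    """
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    df = k - 1
    ranks = np.apply_along_axis(stats.rankdata, 1, table)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums ** 2) - 3.0 * n * (k + 1)
    # tie correction
    tie_term = 0.0
    for row in table:
        _, counts = np.unique(row, return_counts=True)
        tie_term += np.sum(counts ** 3 - counts)
    denom = 1.0 - tie_term / (n * k * (k ** 2 - 1))
    if denom <= 0:
        return 0.0, df, 1.0
    chi2 /= denom
    return float(chi2), df, float(stats.chi2.sf(chi2, df))


def nemenyi_test(table: np.ndarray) -> np.ndarray:
    """Nemenyi post-hoc pairwise p-values for a subjects x conditions table.

    The statistic for conditions i, j is the difference of mean within-row
    ranks scaled by sqrt(k(k+1)/(6n)); p-values come from the studentized
    range distribution with k groups and infinite degrees of freedom.
    """
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, table)
    mean_ranks = ranks.mean(axis=0)
    p = np.ones((k, k))
    scale = np.sqrt(k * (k + 1) / (6.0 * n))
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(mean_ranks[i] - mean_ranks[j]) / scale
            pv = float(stats.studentized_range.sf(q * np.sqrt(2), k, np.inf))
            p[i, j] = p[j, i] = min(1.0, pv)
    return p


def compare_conditions(acc_table: pd.DataFrame,
                       density_pair: tuple[str, str] = ("medium", "low"),
                       decoder_cols: tuple = ("lda", "tcn", "stcn"),
                       alpha: float = 0.05) -> dict:
    """Paired statistics over a per-subject accuracy table.

    Expects a DataFrame indexed by subject.  If columns named after the
    density pair exist, a Wilcoxon signed-rank test compares them; if the
    decoder columns exist, a Friedman test (df = 2 for three decoders)
    compares them, followed by a Nemenyi pairwise matrix when significant.
    Fewer than 6 subjects triggers an underpowered warning flag but the
    tests are still computed.
    """
    out: dict = {"n_subjects": len(acc_table), "underpowered": len(acc_table) < 6}
    a, b = density_pair
    if a in acc_table.columns and b in acc_table.columns:
        w, p = wilcoxon_exact(acc_table[a].to_numpy(), acc_table[b].to_numpy())
        out["wilcoxon"] = {"W": w, "p": p, "pair": [a, b]}
    cols = [c for c in decoder_cols if c in acc_table.columns]
    if len(cols) >= 3:
        sub = acc_table[list(cols)].to_numpy()
        chi2, df, p = friedman_test(sub)
        out["friedman"] = {"chi2": chi2, "df": df, "p": p, "conditions": list(cols)}
        if p < alpha:
            out["nemenyi"] = {"p_matrix": nemenyi_test(sub), "conditions": list(cols)}
    return out
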