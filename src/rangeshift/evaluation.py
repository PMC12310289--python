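"""Model accuracy: continuous Boyce index, AUC, TSS, permutation importance.

The Boyce index slides a window across the prediction range and correlates
the predicted-to-expected presence ratio with the window midpoint (Spearman);
it is threshold-free and rank-based. TSS = sensitivity + specificity - 1 at
a threshold, conventionally the 5% omission threshold of presence
predictions. Variable importance follows the shuffle-correlation procedure:
importance = 1 - max(0, cor(original predictions, shuffled-column
predictions)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .models import FittedEnsemble, predict_table
from .occurrences import TrainingTable

log = logging.getLogger(__name__)


@dataclass
class EvalReport:
    boyce: float
    auc: float
    tss: float
    threshold_used: float
    n_presence_eval: int
    n_background_eval: int


def boyce_index(pred_at_presences, pred_at_background,
                n_windows: int = 101, window_frac: float = 0.1) -> float:
    """Continuous Boyce index in [-1, 1].

    Windows of width ``window_frac`` x (background prediction range) are
    centred at ``n_windows`` evenly spaced midpoints; windows without
    background mass are skipped. The index is the Spearman correlation
    between the P/E ratio and the window midpoint.
    """
    p = np.asarray(pred_at_presences, float)
    b = np.asarray(pred_at_background, float)
    if p.size == 0 or b.size == 0:
        raise ValueError("need non-empty presence and background predictions")
    if min(p.min(), b.min()) < -1e-9 or max(p.max(), b.max()) > 1 + 1e-9:
        raise ValueError("predictions must lie in [0, 1]")
    lo, hi = b.min(), b.max()
    half = 0.5 * window_frac * (hi - lo)
    mids = np.linspace(lo, hi, n_windows)
    F, used = [], []
    for m in mids:
        in_b = ((b >= m - half) & (b <= m + half)).mean()
        if in_b <= 0:
            continue
        in_p = ((p >= m - half) & (p <= m + half)).mean()
        F.append(in_p / in_b)
        used.append(m)
    if len(F) < 2:
        raise ValueError("fewer than 2 usable windows; widen window_frac")
    if np.ptp(F) == 0:
        log.warning("P/E ratio constant across windows; Boyce set to 0")
        return 0.0
    rho = spearmanr(F, used).statistic
    return float(rho)


def auc(pos, neg) -> float:
    """Mann-Whitney concordance: P(pos > neg) + 0.5 P(tie)."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need non-empty positive and negative predictions")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def omission_threshold(pred_at_presences, q: float = 0.05) -> float:
    """Empirical q-quantile of presence predictions (linear interpolation).

    Binarizing at this threshold leaves at least (1 - q) of presences
    classified suitable.
    """
    p = np.asarray(pred_at_presences, float)
    if p.size == 0:
        raise ValueError("need non-empty presence predictions")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    return float(np.quantile(p, q, method="linear"))


def tss(pred, labels, threshold: float) -> float:
    """True skill statistic: sensitivity + specificity - 1 at a threshold."""
    pred = np.asarray(pred, float)
    labels = np.asarray(labels, int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    suit = pred >= threshold
    sens = suit[labels == 1].mean()
    spec = (~suit[labels == 0]).mean()
    return float(sens + spec - 1.0)


def evaluate(ens_pred_presence, ens_pred_background, q: float = 0.05,
             n_windows: int = 101, window_frac: float = 0.1) -> EvalReport:
    """Boyce, AUC and TSS of predictions at presences vs. background.

    TSS uses the q omission threshold of the presence predictions and the
    background sample as the contrast class.
    """
    p = np.asarray(ens_pred_presence, float)
    b = np.asarray(ens_pred_background, float)
    thr = omission_threshold(p, q)
    labels = np.concatenate([np.ones(p.size, int), np.zeros(b.size, int)])
    return EvalReport(
        boyce=boyce_index(p, b, n_windows, window_frac),
        auc=auc(p, b),
        tss=tss(np.concatenate([p, b]), labels, thr),
        threshold_used=thr,
        n_presence_eval=int(p.size),
        n_background_eval=int(b.size),
    )


def variable_importance(ens: FittedEnsemble, table: TrainingTable,
                        n_rep: int = 3, seed: int = 0) -> pd.DataFrame:
    """Shuffle-correlation importance of each predictor (and bias).

    Per variable and repetition, the variable's column is permuted, the
    ensemble re-predicts the table, and importance = 1 - max(0, Pearson
    correlation between original and shuffled predictions). Returns a tidy
    frame with per-repetition rows; aggregate with
    ``df.groupby("variable")["importance"].mean()``.
    """
    df = table.data
    base = predict_table(ens, df)
    rng = np.random.default_rng(seed)
    rows = []
    variables = ens.predictors + ["bias"]
    base_sd = base.std()
    for var in variables:
        for rep in range(n_rep):
            shuffled = df.copy()
            shuffled[var] = rng.permutation(shuffled[var].to_numpy())
            pred = predict_table(ens, shuffled)
            if base_sd == 0 or pred.std() == 0:
                log.warning("constant predictions; importance of %s set to 0", var)
                imp = 0.0
            else:
                r = float(np.corrcoef(base, pred)[0, 1])
                imp = 1.0 - max(0.0, r)
            rows.append({"variable": var, "repetition": rep, "importance": imp})
    return pd.DataFrame(rows)
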