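"""Independent straight-line re-implementations used as test oracles.

Deliberately naive: plain loops and exhaustive enumeration, no shared code
with the package under test.
"""

import math


def tolerance_feasible(truth_site, pred_site, freq_tol=0.6, pos_window=1):
    """(position, frequency) pair admissible as a true positive."""
    tp, tf = truth_site
    pp, pf = pred_site
    lo = max(0.0, tf * (1 - freq_tol))
    hi = min(1.0, tf * (1 + freq_tol))
    return abs(pp - tp) <= pos_window and lo <= pf <= hi


def brute_force_matching(truth, preds, freq_tol=0.6, pos_window=1):
    """Exhaustive best one-to-one matching over (position, frequency) tuples.

    Maximizes match count, then minimizes total positional offset; returns
    (count, total_offset).  Exponential — only for small instances.
    """
    feas = [
        [tolerance_feasible(t, p, freq_tol, pos_window) for p in preds] for t in truth
    ]
    best = [0, 0.0]

    def recurse(i, used, count, offset):
        if i == len(truth):
            if count > best[0] or (count == best[0] and offset < best[1]):
                best[0], best[1] = count, offset
            return
        recurse(i + 1, used, count, offset)  # leave truth i unmatched
        for j in range(len(preds)):
            if j not in used and feas[i][j]:
                recurse(
                    i + 1,
                    used | {j},
                    count + 1,
                    offset + abs(truth[i][0] - preds[j][0]),
                )

    recurse(0, frozenset(), 0, 0.0)
    return best[0], best[1]


def straight_line_metrics(y, yhat):
    """All error metrics computed with plain Python loops."""
    n = len(y)
    errors = [abs(a - b) for a, b in zip(y, yhat)]
    rmse = math.sqrt(sum(e * e for e in errors) / n)
    mae = sum(errors) / n
    median_ae = sorted(errors)[(n - 1) // 2]  # lower median
    mod_errors = [e for a, e in zip(y, errors) if a > 0]
    result = {"rmse": rmse, "mae": mae, "median_ae": median_ae}
    if mod_errors:
        result["max_deviation"] = max(mod_errors)
        result["min_deviation"] = min(mod_errors)
    return result


def straight_line_confusion(truth, preds, n_positions, matched_pred_indices):
    """TP/TN/FP/FN recomputed from first principles, given which predictions
    were matched (the matching itself is an input of the classification)."""
    tp = len(matched_pred_indices)
    fn = len(truth) - tp
    truth_positions = {p for p, _ in truth}
    fp = sum(
        1
        for j, (p, f) in enumerate(preds)
        if j not in matched_pred_indices and f > 0 and p not in truth_positions
    )
    tn = n_positions - len(truth) - fp
    return tp, tn, fp, fn
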