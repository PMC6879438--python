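"""Feature-outcome association and MLP prediction of the two-year endpoint.

The association chain mirrors conventional radiomics statistics: Pearson /
Kendall tau-b correlations, univariate binary logistic regression with Wald
intervals (features significant at P <= 0.05 are signature candidates), and
multivariate logistic regression with forward selection driven by the
likelihood-ratio test.

Prediction uses a single-hidden-layer tanh multilayer perceptron with a
softmax-equivalent output, trained by back-propagation on repeated
stratified 70/30 train/validation splits (five repetitions, as the number
of random weight initializations and splits).  Inputs are standardized on
the training split only; validation AUC is the rank-statistic AUC of the
predicted probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .survival import auc_mann_whitney

__all__ = [
    "LogisticFit",
    "SelectionResult",
    "MLPRunResult",
    "correlate",
    "logistic_univariate",
    "forward_select",
    "mlp_predict_2ypfs",
    "run_prediction_experiment",
]


@dataclass
class LogisticFit:
    coef: float
    intercept: float
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    log_likelihood: float
    converged: bool


@dataclass
class SelectionResult:
    selected: list
    lr_statistics: list
    lr_p_values: list
    final_fit: object | None = None


@dataclass
class MLPRunResult:
    """Per-repetition split metrics plus median/range summaries."""

    repeats: pd.DataFrame      # columns: repeat, auc, train_acc, val_acc, n_train, n_val
    median_auc: float
    auc_range: tuple[float, float]
    median_train_acc: float
    median_val_acc: float
    inputs: list = field(default_factory=list)


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided p-value.

    ``pearson`` uses the t-approximation; ``kendall_tau_b`` uses the
    tie-corrected tau-b with its normal-approximation p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method in ("kendall", "kendall_tau_b"):
        res = stats.kendalltau(x, y, variant="b", method="asymptotic")
        r, p = res.statistic, res.pvalue
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def _check_binary_outcome(outcome) -> np.ndarray:
    y = np.asarray(outcome).astype(float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("outcome must be binary 0/1")
    if classes.size < 2:
        raise ValueError("outcome has a single class; logistic fit undefined")
    return y


def logistic_univariate(feature, outcome) -> LogisticFit:
    """Maximum-likelihood univariate logistic fit with Wald CI for the OR."""
    x = np.asarray(feature, dtype=float)
    y = _check_binary_outcome(outcome)
    if x.size != y.size:
        raise ValueError("feature and outcome must have equal length")
    if x.size < 10:
        raise ValueError("need at least 10 subjects")
    design = sm.add_constant(x)
    model = sm.Logit(y, design)
    try:
        res = model.fit(disp=0, maxiter=200, method="newton", tol=1e-10)
    except Exception as exc:
        raise ValueError(f"logistic fit failed (possible separation): {exc}") from exc
    grad = model.score(res.params)
    if not res.mle_retvals.get("converged", False) and np.linalg.norm(grad) > 1e-6:
        raise ValueError("logistic fit did not converge (possible separation)")
    coef = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(se) or se > 50:
        raise ValueError("logistic fit unstable (possible complete separation)")
    z = stats.norm.ppf(0.975)
    return LogisticFit(
        coef=coef,
        intercept=float(res.params[0]),
        odds_ratio=float(np.exp(coef)),
        ci_lower=float(np.exp(coef - z * se)),
        ci_upper=float(np.exp(coef + z * se)),
        p_value=float(res.pvalues[1]),
        log_likelihood=float(res.llf),
        converged=True,
    )


def _fit_multivariate(x: np.ndarray, y: np.ndarray):
    design = sm.add_constant(x, has_constant="add")
    return sm.Logit(y, design).fit(disp=0, maxiter=200)


def forward_select(
    candidates: pd.DataFrame, outcome, entry_p: float = 0.05
) -> SelectionResult:
    """Forward stepwise logistic selection by likelihood-ratio p-value.

    Starting from the intercept-only model, the candidate with the smallest
    likelihood-ratio p enters while that p is at or below ``entry_p``; ties
    are broken by column order.
    """
    if candidates.shape[1] < 1:
        raise ValueError("need at least one candidate feature")
    y = _check_binary_outcome(outcome)
    x_all = candidates.to_numpy(dtype=float)
    names = list(candidates.columns)
    selected: list = []
    lr_stats: list = []
    lr_ps: list = []
    ll_current = float(sm.Logit(y, np.ones((y.size, 1))).fit(disp=0).llf)
    current_idx: list = []
    final = None
    while True:
        best = None
        for j, name in enumerate(names):
            if name in selected:
                continue
            try:
                res = _fit_multivariate(x_all[:, current_idx + [j]], y)
            except Exception:
                # singular design (e.g. a duplicate of an entered feature)
                continue
            lr = 2.0 * (float(res.llf) - ll_current)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            if best is None or p < best[0] - 1e-15:
                best = (p, lr, j, name, res)
        if best is None or best[0] > entry_p:
            break
        p, lr, j, name, res = best
        selected.append(name)
        lr_stats.append(lr)
        lr_ps.append(p)
        current_idx.append(j)
        ll_current = float(res.llf)
        final = res
    return SelectionResult(
        selected=selected, lr_statistics=lr_stats, lr_p_values=lr_ps, final_fit=final
    )


# ---------------------------------------------------------------------------
# MLP prediction
# ---------------------------------------------------------------------------

def _stratified_split(y: np.ndarray, train_frac: float, rng: np.random.Generator):
    """Outcome-stratified random split; both classes guaranteed in training."""
    idx_train, idx_val = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_tr = int(round(train_frac * idx.size))
        n_tr = min(max(n_tr, 1), idx.size - 1) if idx.size > 1 else n_tr
        idx_train.append(idx[:n_tr])
        idx_val.append(idx[n_tr:])
    return np.sort(np.concatenate(idx_train)), np.sort(np.concatenate(idx_val))


def mlp_predict_2ypfs(
    features: pd.DataFrame,
    outcome,
    n_repeats: int = 5,
    train_frac: float = 0.70,
    hidden_neurons: int = 4,
    seed: int = 0,
    max_epochs: int = 2000,
) -> MLPRunResult:
    """Repeated-split MLP prediction of the two-year endpoint.

    Each repetition draws a fresh stratified 70/30 split and a fresh weight
    initialization, standardizes inputs on the training split, trains a
    one-hidden-layer tanh network (softmax-equivalent logistic output) by
    gradient-based back-propagation with early stopping on an inner
    validation slice, and records the validation AUC plus train/validation
    accuracies at probability 0.5.
    """
    from sklearn.neural_network import MLPClassifier
    from sklearn.preprocessing import StandardScaler

    if hidden_neurons < 3:
        raise ValueError("at least three hidden neurons are required")
    y = _check_binary_outcome(outcome)
    x = features.to_numpy(dtype=float)
    if x.shape[0] < 20:
        raise ValueError("need at least 20 subjects")
    rng = np.random.default_rng([int(seed) % (2 ** 31), 7])
    rows = []
    for rep in range(n_repeats):
        for attempt in range(100):
            tr, va = _stratified_split(y, train_frac, rng)
            if np.unique(y[tr]).size == 2 and va.size > 0:
                break
        else:
            raise ValueError("could not draw a split with both classes in training")
        scaler = StandardScaler().fit(x[tr])
        xt, xv = scaler.transform(x[tr]), scaler.transform(x[va])
        clf = MLPClassifier(
            hidden_layer_sizes=(hidden_neurons,),
            activation="tanh",
            solver="adam",
            learning_rate_init=0.01,
            max_iter=max_epochs,
            early_stopping=True,
            validation_fraction=0.1,
            n_iter_no_change=50,
            random_state=int(rng.integers(2 ** 31)),
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(xt, y[tr])
        p_tr = clf.predict_proba(xt)[:, 1]
        p_va = clf.predict_proba(xv)[:, 1]
        auc = (
            auc_mann_whitney(p_va, y[va].astype(bool))
            if np.unique(y[va]).size == 2
            else np.nan
        )
        rows.append(
            {
                "repeat": rep,
                "auc": auc,
                "train_acc": float(((p_tr > 0.5) == y[tr].astype(bool)).mean()),
                "val_acc": float(((p_va > 0.5) == y[va].astype(bool)).mean()),
                "n_train": int(tr.size),
                "n_val": int(va.size),
            }
        )
    rep_df = pd.DataFrame(rows)
    aucs = rep_df["auc"].dropna()
    return MLPRunResult(
        repeats=rep_df,
        median_auc=float(aucs.median()),
        auc_range=(float(aucs.min()), float(aucs.max())),
        median_train_acc=float(rep_df["train_acc"].median()),
        median_val_acc=float(rep_df["val_acc"].median()),
        inputs=list(features.columns),
    )


RADIOMIC_INPUTS = ["suv_mean", "entropy"]
CLINICAL_INPUTS = ["ecog", "wbc", "ldh", "ki67"]


def run_prediction_experiment(
    features: pd.DataFrame,
    patients: pd.DataFrame,
    mode: str = "both",
    outcome_col: str = "pfs2y_event",
    n_repeats: int = 5,
    train_frac: float = 0.70,
    hidden_neurons: int = 4,
    seed: int = 0,
) -> dict[str, MLPRunResult]:
    """Run the radiomic-only and radiomic+clinical MLP experiments.

    ``features`` must carry ``patient_id, suv_mean, entropy``; ``patients``
    the clinical inputs and the binary outcome column.
    """
    if mode not in ("radiomic_only", "radiomic_plus_clinical", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    merged = features.merge(patients, on="patient_id", validate="1:1")
    out: dict[str, MLPRunResult] = {}
    modes = (
        ["radiomic_only", "radiomic_plus_clinical"] if mode == "both" else [mode]
    )
    for m in modes:
        cols = RADIOMIC_INPUTS + (CLINICAL_INPUTS if m == "radiomic_plus_clinical" else [])
        out[m] = mlp_predict_2ypfs(
            merged[cols],
            merged[outcome_col].astype(int),
            n_repeats=n_repeats,
            train_frac=train_frac,
            hidden_neurons=hidden_neurons,
            seed=seed,
        )
    return out
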