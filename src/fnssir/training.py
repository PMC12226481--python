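"""Training loops, cross-validation schemes, metrics, and significance tests.

Defaults follow the study protocol: Adam (lr = 0.001), cross-entropy loss,
200 training epochs with batch size 7 for the within-session protocol (400
epochs / batch 36 for the session-split benchmark style), 4-fold stratified
cross-validation repeated 5 times.  The repeat-level summary reports both the
highest repeat mean (the protocol's headline convention) and the grand mean
across repeats (the less optimistic figure, recommended).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .epochs import EpochSet
from .model import FNSSIR, ModelConfig, minmax_scale
from .plane import GridMap, build_grid

__all__ = [
    "TrainConfig", "TrainResult", "EvalReport", "CVReport",
    "DegenerateTTestError", "stratified_kfold", "cae_recon_target", "train",
    "evaluate", "cv_experiment", "loso_experiment", "paired_ttest",
    "label_shuffled", "chance_bounds",
]


class DegenerateTTestError(ValueError):
    """Paired differences have zero variance; the t statistic is undefined."""


@dataclass
class TrainConfig:
    epochs: int = 200            # 400 for the session-split style
    lr: float = 1e-3
    batch_size: int = 7          # 36 for the session-split style
    seed: int = 0
    folds: int = 4
    repeats: int = 5
    lambda_recon: float = 0.1
    recon_lowpass_hz: float = 5.0
    log_every: int = 0           # epochs between stderr loss lines; 0 = silent


@dataclass
class TrainResult:
    loss_trace: list[float]
    ce_trace: list[float]
    model: FNSSIR


@dataclass
class EvalReport:
    accuracy: float                  # percent
    confusion: np.ndarray            # [n_classes, n_classes] counts
    n_test: int
    scheme: str = ""
    seed: int | None = None

    def validate(self) -> None:
        if int(self.confusion.sum()) != self.n_test:
            raise ValueError("confusion counts do not sum to the test size")
        acc = 100.0 * np.trace(self.confusion) / max(self.n_test, 1)
        if abs(acc - self.accuracy) > 1e-9:
            raise ValueError("accuracy inconsistent with the confusion trace")


@dataclass
class CVReport:
    per_fold_acc: list[list[float]]      # [repeat][fold], percent
    repeat_means: list[float]
    best_repeat_mean: float              # protocol headline convention
    grand_mean: float                    # recommended summary
    std_acc: float                       # across all folds of all repeats
    confusion: np.ndarray
    seed: int
    scheme: str = "stratified-kfold"


def stratified_kfold(labels: np.ndarray, k: int, seed: int):
    """Shuffled stratified k-fold; per-class fold counts differ by <= 1."""
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels)
    counts = np.bincount(labels)
    if (counts[counts > 0] < k).any():
        small = int(np.flatnonzero((counts > 0) & (counts < k))[0])
        raise ValueError(f"class {small} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2 ** 32))
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def cae_recon_target(epochs: EpochSet, channels, lowpass_hz: float = 5.0
                     ) -> np.ndarray:
    """[n, 1, C_m, T] min-max-scaled low-passed signals: the denoising target."""
    import mne

    rows = np.stack([epochs.get_channel(c) for c in channels], axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        low = mne.filter.filter_data(rows.astype(np.float64), sfreq=epochs.fs,
                                     l_freq=None, h_freq=lowpass_hz, verbose=False)
    return minmax_scale(low)[:, None].reshape(rows.shape[0], 1, rows.shape[1], -1)


def train(model: FNSSIR, epochs_data: EpochSet, grid: GridMap | None,
          tcfg: TrainConfig | None = None) -> TrainResult:
    """Supervised training with Adam and cross-entropy (+ lambda * recon MSE)."""
    import sys

    tcfg = tcfg or TrainConfig()
    plane_x, cae_x = model.prepare_inputs(epochs_data, grid)
    labels = epochs_data.labels
    target = None
    if model.has_cae and tcfg.lambda_recon > 0:
        target = cae_recon_target(epochs_data, model.cfg.cae_channels,
                                  tcfg.recon_lowpass_hz).astype(model.dtype)
    opt = nn.Adam(model.params(), lr=tcfg.lr)
    rng = np.random.default_rng(tcfg.seed)
    n = epochs_data.n_trials
    loss_trace, ce_trace = [], []
    for ep in range(tcfg.epochs):
        perm = rng.permutation(n)
        ep_loss = ep_ce = 0.0
        for i in range(0, n, tcfg.batch_size):
            idx = perm[i:i + tcfg.batch_size]
            opt.zero_grad()
            logits, recon = model.forward(
                None if plane_x is None else plane_x[idx],
                None if cae_x is None else cae_x[idx], training=True)
            ce, dlogits = nn.softmax_cross_entropy(logits, labels[idx])
            loss = ce
            drecon = None
            if target is not None:
                m, dm = nn.mse_loss(recon, target[idx])
                loss = ce + tcfg.lambda_recon * m
                drecon = (tcfg.lambda_recon * dm).astype(model.dtype)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"loss became non-finite (lr={tcfg.lr}, epoch={ep}, "
                    f"batch={i // tcfg.batch_size})")
            model.backward(dlogits, drecon)
            opt.step()
            ep_loss += loss * len(idx)
            ep_ce += ce * len(idx)
        loss_trace.append(ep_loss / n)
        ce_trace.append(ep_ce / n)
        if tcfg.log_every and (ep + 1) % tcfg.log_every == 0:
            print(f"epoch {ep + 1}/{tcfg.epochs} loss={loss_trace[-1]:.4f}",
                  file=sys.stderr)
    return TrainResult(loss_trace, ce_trace, model)


def evaluate(model: FNSSIR, test_epochs: EpochSet, grid: GridMap | None,
             scheme: str = "", seed: int | None = None) -> EvalReport:
    from sklearn.metrics import confusion_matrix

    if test_epochs.n_trials == 0:
        raise ValueError("empty test set")
    plane_x, cae_x = model.prepare_inputs(test_epochs, grid)
    pred = model.predict(plane_x, cae_x)
    cm = confusion_matrix(test_epochs.labels, pred,
                          labels=np.arange(model.cfg.n_classes))
    acc = 100.0 * np.trace(cm) / test_epochs.n_trials
    report = EvalReport(float(acc), cm, test_epochs.n_trials, scheme, seed)
    report.validate()
    return report


def _fit_eval_split(epochs_data, train_idx, test_idx, model_cfg, grid, tcfg,
                    model_seed):
    if np.intersect1d(train_idx, test_idx).size:
        raise AssertionError("information leak: train and test folds overlap")
    model = FNSSIR(model_cfg, seed=model_seed)
    train(model, epochs_data.select_trials(train_idx), grid, tcfg)
    return evaluate(model, epochs_data.select_trials(test_idx), grid)


def cv_experiment(epochs_data: EpochSet, model_cfg: ModelConfig | None = None,
                  tcfg: TrainConfig | None = None, grid: GridMap | None = None,
                  ) -> CVReport:
    """k-fold CV repeated ``tcfg.repeats`` times (repeat r seeds with seed+r)."""
    model_cfg = model_cfg or ModelConfig()
    tcfg = tcfg or TrainConfig()
    if grid is None and model_cfg.ablate_component != "MSSTCN":
        grid = build_grid(epochs_data.channel_names, model_cfg.grid_shape)
    per_fold, repeat_means = [], []
    confusion = np.zeros((model_cfg.n_classes, model_cfg.n_classes), dtype=int)
    for r in range(tcfg.repeats):
        seed_r = tcfg.seed + r
        folds = stratified_kfold(epochs_data.labels, tcfg.folds, seed_r)
        accs = []
        for fi, (tr, te) in enumerate(folds):
            rep = _fit_eval_split(
                epochs_data, tr, te, model_cfg, grid,
                TrainConfig(**{**tcfg.__dict__, "seed": seed_r}),
                model_seed=seed_r * 1000 + fi)
            accs.append(rep.accuracy)
            confusion += rep.confusion
        per_fold.append(accs)
        repeat_means.append(float(np.mean(accs)))
    flat = np.concatenate(per_fold)
    return CVReport(per_fold, repeat_means, float(np.max(repeat_means)),
                    float(np.mean(repeat_means)), float(np.std(flat)),
                    confusion, tcfg.seed)


def loso_experiment(subjects: list[EpochSet], model_cfg: ModelConfig | None = None,
                    tcfg: TrainConfig | None = None) -> dict[str, EvalReport]:
    """Leave-one-subject-out: train on all but one subject, test on the rest."""
    from dataclasses import replace as _replace

    model_cfg = model_cfg or ModelConfig()
    tcfg = tcfg or TrainConfig()
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    for s in subjects:
        if s.n_trials == 0:
            raise ValueError(f"subject {s.subject_id} has no trials")
    grid = None
    if model_cfg.ablate_component != "MSSTCN":
        grid = build_grid(subjects[0].channel_names, model_cfg.grid_shape)
    out = {}
    for i, held in enumerate(subjects):
        rest = [s for j, s in enumerate(subjects) if j != i]
        pooled = EpochSet(
            np.concatenate([s.data for s in rest]),
            np.concatenate([s.labels for s in rest]),
            rest[0].channel_names, rest[0].fs, rest[0].t0, subject_id="pooled")
        model = FNSSIR(model_cfg, seed=tcfg.seed + i)
        train(model, pooled, grid, tcfg)
        out[held.subject_id] = evaluate(model, held, grid, scheme="loso",
                                        seed=tcfg.seed + i)
    return out


def paired_ttest(acc_a, acc_b):
    """Two-sided paired-sample t-test on per-subject accuracies.

    Returns (t, p).  Warns (advisory, not a gate) when a Shapiro-Wilk test
    suggests the paired differences depart from normality.
    """
    from scipy import stats

    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length vectors with at least 3 entries")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateTTestError(
            "paired differences have zero variance; t-test undefined")
    if a.size >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw_p = stats.shapiro(d).pvalue
        if sw_p < 0.05:
            warnings.warn(f"paired differences may be non-normal "
                          f"(Shapiro-Wilk p = {sw_p:.3g})", stacklevel=2)
    n = a.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def label_shuffled(epochs_data: EpochSet, seed: int) -> EpochSet:
    """Copy with labels permuted: the chance-level control."""
    rng = np.random.default_rng(seed)
    from dataclasses import replace as _replace
    return _replace(epochs_data, labels=rng.permutation(epochs_data.labels))


def chance_bounds(n_per_fold: int, n_classes: int = 3, conf: float = 0.99):
    """Binomial confidence band (percent) around chance for one fold."""
    from scipy import stats

    lo, hi = stats.binom.interval(conf, n_per_fold, 1.0 / n_classes)
    return 100.0 * lo / n_per_fold, 100.0 * hi / n_per_fold
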