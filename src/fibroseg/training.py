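"""Five-fold cross-validation training protocol.

Studies are split into k folds; for each fold a fresh network is trained on
the slices of the other k−1 folds (with on-the-fly geometric augmentation and
fold-specific pixel-wise standardization) and validated on the held-out fold.
Training minimizes the Tversky loss (alpha = 0.3, beta = 0.7) with Adam, a
batch of 8 slices, and stops when the epoch-mean training loss has not
improved for 10 consecutive epochs (or at 100 epochs). A held-out test set,
never seen by any fold, is scored by every fold model and the metrics are
averaged across the five models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .architectures import NetworkHandle, build_model
from .metrics import MetricsReport, SummaryStats, TverskyParams, compute_metrics, summarize, tversky_loss_from_probs
from .nn.optim import Adam
from .preprocess import StandardizationStats, apply_standardization, compute_standardization, extract_slices
from .volume import CTVolume, MaskVolume, SlicePair

Study = tuple[CTVolume, MaskVolume]


# ---------------------------------------------------------------------------
# fold bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    """Random partition of study ids into k folds (k−1 of size ⌊n/k⌋, one
    absorbing the remainder)."""

    k: int
    fold_assignment: dict[str, int]
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_assignment.items() if f == fold]

    def training_ids(self, val_fold: int) -> list[str]:
        return [s for s, f in self.fold_assignment.items() if f != val_fold]

    def sizes(self) -> list[int]:
        return [len(self.fold_ids(f)) for f in range(self.k)]


def make_folds(study_ids, k: int = 5, seed: int = 0) -> FoldSplit:
    """Randomly assign studies to k folds; deterministic for a fixed seed."""
    ids = list(study_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate study ids")
    if len(ids) < k:
        raise ValueError(f"need at least k={k} studies, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    base = len(ids) // k
    assignment: dict[str, int] = {}
    pos = 0
    for f in range(k):
        size = base if f < k - 1 else len(ids) - base * (k - 1)
        for s in perm[pos:pos + size]:
            assignment[s] = f
        pos += size
    return FoldSplit(k, assignment, seed)


def stratified_split(study_keys: dict[str, str], n_test: int,
                     seed: int = 0) -> tuple[list[str], list[str]]:
    """Split ids into train/test keeping the composition of `study_keys`
    (e.g. scanner tag) approximately equal in both parts."""
    rng = np.random.default_rng(seed)
    by_key: dict[str, list[str]] = {}
    for sid, key in study_keys.items():
        by_key.setdefault(key, []).append(sid)
    n = len(study_keys)
    test: list[str] = []
    for key in sorted(by_key):
        group = sorted(by_key[key])
        take = int(round(n_test * len(group) / n))
        picks = rng.permutation(len(group))[:take]
        test += [group[i] for i in picks]
    # adjust to exactly n_test
    remaining = [s for s in study_keys if s not in test]
    while len(test) > n_test:
        remaining.append(test.pop())
    while len(test) < n_test:
        test.append(remaining.pop(int(rng.integers(len(remaining)))))
    train = [s for s in study_keys if s not in test]
    return train, test


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentationConfig:
    """Six geometric augmentation modes with mild conventional ranges."""

    rotation_deg: float = 10.0
    shift_x: float = 0.10        # fraction of width
    shift_y: float = 0.10        # fraction of height
    shear_deg: float = 5.0
    flip_prob: float = 0.5
    zoom_range: tuple[float, float] = (0.9, 1.1)
    fill_value: float = -1000.0  # air, applied before standardization

    def validate(self) -> None:
        for v in (self.rotation_deg, self.shift_x, self.shift_y, self.shear_deg):
            if not math.isfinite(v):
                raise ValueError("augmentation ranges must be finite")
        if not 0 <= self.flip_prob <= 1:
            raise ValueError("flip_prob must be in [0, 1]")


def identity_augmentation() -> AugmentationConfig:
    return AugmentationConfig(0.0, 0.0, 0.0, 0.0, 0.0, (1.0, 1.0))


def augment_pair(pair: SlicePair, cfg: AugmentationConfig,
                 rng: np.random.Generator) -> SlicePair:
    """Apply one randomly sampled geometric transform to image and mask.

    The image is interpolated linearly, the mask with nearest neighbour (so
    it stays binary); the identical transform is used for both.
    """
    cfg.validate()
    theta = math.radians(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
    shear = math.radians(rng.uniform(-cfg.shear_deg, cfg.shear_deg))
    zoom = rng.uniform(*cfg.zoom_range)
    h, w = pair.image.shape
    tx = rng.uniform(-cfg.shift_x, cfg.shift_x) * w
    ty = rng.uniform(-cfg.shift_y, cfg.shift_y) * h
    flip = rng.random() < cfg.flip_prob

    # output-to-input map: rotate+shear+zoom about the center, then shift
    cos, sin = math.cos(theta), math.sin(theta)
    fwd = np.array([[cos, -sin + math.tan(shear)], [sin, cos]]) * zoom
    inv = np.linalg.inv(fwd)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - inv @ center - inv @ np.array([tx, ty])

    img = ndimage.affine_transform(pair.image.astype(np.float64), inv, offset=offset,
                                   order=1, cval=cfg.fill_value, output_shape=(h, w))
    msk = ndimage.affine_transform(pair.mask, inv, offset=offset, order=0, cval=0,
                                   output_shape=(h, w))
    if flip:
        img = img[:, ::-1].copy()
        msk = msk[:, ::-1].copy()
    return SlicePair(img, msk, pair.study_id, pair.slice_index)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    model: str = "enet"              # unet3 | unet5 | enet
    learning_rate: float | None = None  # default per model: 1e-4 enet, 1e-5 unet
    batch_size: int = 8
    max_epochs: int = 100
    patience: int = 10
    tversky: TverskyParams = field(default_factory=TverskyParams)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    smooth: float = 1e-6
    clip_norm: float | None = 1.0   # global gradient-norm clip
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.patience < self.max_epochs:
            raise ValueError("require 0 < patience < max_epochs")
        if self.learning_rate is not None and self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")

    @property
    def lr(self) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return 1e-4 if self.model == "enet" else 1e-5


@dataclass
class TrainingLog:
    loss: list[float] = field(default_factory=list)
    dsc: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    stop_reason: str = ""

    def as_dict(self) -> dict:
        return asdict(self)


def _batch_arrays(pairs: list[SlicePair], stats: StandardizationStats):
    imgs = np.stack([apply_standardization(p.image, stats) for p in pairs])
    msks = np.stack([p.mask for p in pairs])
    return imgs[:, None].astype(np.float32), msks[:, None].astype(np.float32)


def train_model(net: NetworkHandle, training_slices: list[SlicePair],
                stats: StandardizationStats, cfg: TrainConfig,
                loss_hook=None) -> TrainingLog:
    """Mini-batch Adam on the Tversky loss with on-the-fly augmentation.

    `training_slices` are raw (HU) slices of the training folds;
    augmentation happens before standardization. Stops when the epoch-mean
    loss has shown no strict improvement for `patience` consecutive epochs.
    `loss_hook(epoch)` may inject a synthetic epoch loss (used to unit-test
    the stopping arithmetic without real optimization).
    """
    cfg.validate()
    if not training_slices:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam([p for p in net.parameters()], lr=cfg.lr, clip_norm=cfg.clip_norm)
    log = TrainingLog()
    best = math.inf
    bad_epochs = 0
    n = len(training_slices)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        total_loss, total_w = 0.0, 0
        tp = fp = fn = 0
        for start in range(0, n, cfg.batch_size):
            batch = [training_slices[i] for i in order[start:start + cfg.batch_size]]
            batch = [augment_pair(p, cfg.augmentation, rng) for p in batch]
            x, g = _batch_arrays(batch, stats)
            opt.zero_grad()
            probs = net.forward(x, training=True, rng=rng)
            loss = tversky_loss_from_probs(probs, g, cfg.tversky, cfg.smooth)
            loss.backward()
            net.collect_grads()
            opt.step()
            for p in net.parameters():
                p.grad = None
            total_loss += loss.item() * len(batch)
            total_w += len(batch)
            hard = (probs.data[:, 0] >= probs.data[:, 1]).astype(np.uint8)
            gt = g[:, 0] > 0.5
            tp += int((hard.astype(bool) & gt).sum())
            fp += int((hard.astype(bool) & ~gt).sum())
            fn += int((~hard.astype(bool) & gt).sum())
        epoch_loss = total_loss / total_w
        if loss_hook is not None:
            epoch_loss = loss_hook(epoch)
        epoch_dsc = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
        log.loss.append(epoch_loss)
        log.dsc.append(epoch_dsc)
        if epoch_loss < best:
            best = epoch_loss
            bad_epochs = 0
        else:
            bad_epochs += 1
        if bad_epochs >= cfg.patience:
            log.stopped_epoch, log.stop_reason = epoch, "patience"
            return log
    log.stopped_epoch, log.stop_reason = cfg.max_epochs, "max_epochs"
    return log


def predict_study(net: NetworkHandle, vol: CTVolume,
                  stats: StandardizationStats, batch_size: int = 8) -> MaskVolume:
    """Per-slice inference: standardize, forward, arg-max (lung = channel 0)."""
    if vol.voxels.shape[:2] != stats.mean_image.shape:
        raise ValueError(
            f"volume plane {vol.voxels.shape[:2]} does not match model input "
            f"{stats.mean_image.shape}")
    planes = np.stack([apply_standardization(vol.voxels[:, :, k], stats)
                       for k in range(vol.shape[2])])
    probs = net.predict_probs(planes[:, None].astype(np.float32), batch_size)
    lung = (probs[:, 0] >= probs[:, 1]).astype(np.uint8)
    return MaskVolume(np.moveaxis(lung, 0, 2), vol.spacing, vol.study_id)


# ---------------------------------------------------------------------------
# cross-validation and held-out evaluation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    fold: int
    net: NetworkHandle
    stats: StandardizationStats
    log: TrainingLog
    train_ids: list[str]
    val_ids: list[str]
    val_reports: dict[str, MetricsReport]


def _training_slices(studies: dict[str, Study], ids) -> list[SlicePair]:
    out: list[SlicePair] = []
    for sid in ids:
        vol, mask = studies[sid]
        out += extract_slices(vol, mask)
    return out


def cross_validate(model_kind: str, studies: dict[str, Study], cfg: TrainConfig,
                   k: int = 5, model_overrides: dict | None = None
                   ) -> tuple[list[FoldResult], dict[str, SummaryStats]]:
    """Train k fold models, each validated on its held-out fold.

    Standardization statistics are computed from the k−1 training folds only;
    the leakage audit (validation ids disjoint from training ids) is asserted
    per fold. Returns the per-fold results and per-metric summaries over all
    validation studies.
    """
    folds = make_folds(studies.keys(), k=k, seed=cfg.seed)
    results: list[FoldResult] = []
    for f in range(k):
        train_ids = folds.training_ids(f)
        val_ids = folds.fold_ids(f)
        assert not set(train_ids) & set(val_ids), "fold leakage"
        slices = _training_slices(studies, train_ids)
        stats = compute_standardization(slices, fold_id=f)
        net = build_model(model_kind, seed=cfg.seed + 1000 + f,
                          **(model_overrides or {}))
        fold_cfg = TrainConfig(**{**asdict(cfg), "seed": cfg.seed + f,
                                  "tversky": cfg.tversky,
                                  "augmentation": cfg.augmentation,
                                  "model": model_kind})
        log = train_model(net, slices, stats, fold_cfg)
        reports = {}
        for sid in val_ids:
            vol, truth = studies[sid]
            pred = predict_study(net, vol, stats)
            reports[sid] = compute_metrics(pred, truth)
        results.append(FoldResult(f, net, stats, log, train_ids, val_ids, reports))
    summary = _summarize_reports([r for res in results for r in res.val_reports.values()])
    return results, summary


def _summarize_reports(reports: list[MetricsReport]) -> dict[str, SummaryStats]:
    return {key: summarize([rep.as_dict()[key] for rep in reports])
            for key in ("sensitivity", "ppv", "dsc", "voe", "vd", "assd")}


def evaluate_testset(fold_models: list[tuple[NetworkHandle, StandardizationStats]],
                     test_studies: dict[str, Study],
                     train_ids: set[str]
                     ) -> tuple[list[tuple[int, str, MetricsReport]],
                                dict[str, SummaryStats]]:
    """Score a held-out test set with every fold model.

    Metrics are computed per (model, study) and the reported summaries are
    averages across the fold models, one value per metric per study first
    averaged over models. A test id overlapping the training ids is an error.
    """
    overlap = set(test_studies) & set(train_ids)
    if overlap:
        raise ValueError(f"test studies {sorted(overlap)} were used in training")
    rows: list[tuple[int, str, MetricsReport]] = []
    for i, (net, stats) in enumerate(fold_models):
        for sid, (vol, truth) in test_studies.items():
            pred = predict_study(net, vol, stats)
            rows.append((i, sid, compute_metrics(pred, truth)))
    summary = _summarize_reports([rep for _, _, rep in rows])
    return rows, summary
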