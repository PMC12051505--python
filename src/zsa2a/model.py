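"""Zero-shot artifact removal for sparse-array photoacoustic reconstructions.

The method exploits the fact that sparse-array reconstruction artifacts
fluctuate strongly under random detector loss while true absorber signals do
not.  From the sparse channel data, two detector subsets are drawn by random
discarding and reconstructed independently (``recon1``, ``recon2``).  A tiny
image-to-image network g_theta is then trained *on this image pair alone* to
predict the artifact component, by minimising

    L_res  = 1/2 ( ||recon1 - g(recon1) - recon2||^2
                 + ||recon2 - g(recon2) - recon1||^2 )
    L_cons = ||(recon1 - g(recon1)) - (recon2 - g(recon2))||^2
    L      = L_res + L_cons

where ``||.||^2`` denotes the mean of squared entries (so the learning rate
is image-size independent).  The trained network is applied to the sparse
reconstruction ``recon0`` and the cleaned image is
``clean = recon0 - g(recon0)``.  No external data, pretraining or stored
weights are involved: training is per image (per slice for 3-D volumes).

The public surface follows the Model/Results convention: build a
:class:`ZSA2A` model from a reconstruction pair, call :meth:`ZSA2A.fit` to
obtain a :class:`ZSA2AResults`, then :meth:`ZSA2AResults.decompose` any
image reconstructed from the same data.
"""

from __future__ import annotations

import dataclasses
import io

import numpy as np
import pandas as pd

from .nn import Adam, TinyConvNet, step_lr
from .recon import ReconImage, extract_slices, restack

__all__ = [
    "DetectorSubset", "sample_subset", "TrainConfig", "ArtifactPredictor",
    "predict_artifact", "residual_loss", "consistency_loss", "total_loss",
    "multi_subset_losses", "LossBreakdown", "TrainingDivergedError",
    "ZSA2A", "ZSA2AResults", "fit", "DecompositionResult", "decompose",
    "run_zsa2a_slicewise",
]


# ---------------------------------------------------------------------------
# subset generation


@dataclasses.dataclass(frozen=True)
class DetectorSubset:
    """The index set kept after randomly discarding detectors (M of N)."""

    indices: np.ndarray
    parent_n: int
    label: int = 1

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1 or idx.size < 1:
            raise ValueError("indices must be a non-empty 1-D sequence")
        if len(np.unique(idx)) != idx.size:
            raise ValueError("subset indices must be unique")
        if idx.min() < 0 or idx.max() >= self.parent_n:
            raise ValueError("subset indices must lie in [0, parent_n)")
        object.__setattr__(self, "indices", idx)

    @property
    def m(self) -> int:
        return self.indices.size


def sample_subset(n: int, m: int, seed: int = 0, label: int = 1) -> DetectorSubset:
    """Draw ``m`` of ``n`` detector indices uniformly without replacement.

    Different ``label`` values give independent streams for the same ``seed``,
    so the two (or more) subsets of one run may overlap but are independent.
    Indices are returned sorted.
    """
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, {n}], got {m}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(label,)))
    idx = np.sort(rng.choice(n, size=m, replace=False))
    return DetectorSubset(idx, n, label)


# ---------------------------------------------------------------------------
# configuration and the predictor


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the per-image training run.

    Defaults are the method's standard settings: 3000 Adam iterations at
    lr 0.01 with a step decay (x0.6 every 1000 iterations), two detector
    subsets.  ``subset_size`` is the M of the random-discard step; ``None``
    leaves it to the caller.
    """

    iterations: int = 3000
    lr: float = 0.01
    step_size: int = 1000
    gamma: float = 0.6
    seed: int = 0
    n_subsets: int = 2
    subset_size: int | None = None
    hidden_channels: int = 48
    negative_slope: float = 0.1
    normalize: bool = False

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if self.n_subsets < 2:
            raise ValueError("n_subsets must be >= 2")
        if self.lr <= 0 or self.step_size < 1:
            raise ValueError("lr must be positive and step_size >= 1")

    def replace(self, **kw) -> "TrainConfig":
        return dataclasses.replace(self, **kw)


class ArtifactPredictor:
    """The trained artifact network g_theta plus its input scaling.

    ``predict`` maps an image to a same-shape artifact estimate; with all-zero
    parameters the output is identically zero.
    """

    def __init__(self, net: TinyConvNet, input_scale: float = 1.0):
        self.net = net
        self.input_scale = float(input_scale)

    @classmethod
    def zeros(cls, hidden_channels: int = 48) -> "ArtifactPredictor":
        return cls(TinyConvNet(hidden_channels).zero_())

    @property
    def parameters(self) -> dict:
        return self.net.state_dict()

    @property
    def parameter_count(self) -> int:
        return self.net.parameter_count

    @property
    def architecture(self) -> tuple:
        return self.net.architecture

    def predict(self, image: np.ndarray | ReconImage) -> np.ndarray:
        x = _values(image)
        s = self.input_scale
        out = self.net.forward(np.asarray(x, dtype=np.float32) / s)
        return np.asarray(out, dtype=float) * s

    __call__ = predict


def predict_artifact(model, image) -> np.ndarray:
    """Functional form of :meth:`ArtifactPredictor.predict`."""
    return _apply_g(model, _values(image))


# ---------------------------------------------------------------------------
# losses


def _values(image) -> np.ndarray:
    return np.asarray(image.values if isinstance(image, ReconImage) else image,
                      dtype=float)


def _apply_g(model, x: np.ndarray) -> np.ndarray:
    if isinstance(model, ArtifactPredictor):
        return model.predict(x)
    if isinstance(model, TinyConvNet):
        return np.asarray(model.forward(np.asarray(x, dtype=np.float32)), dtype=float)
    if callable(model):
        return np.asarray(model(x), dtype=float)
    raise TypeError("model must be an ArtifactPredictor, TinyConvNet or callable")


def _check_pair(r1, r2):
    r1, r2 = _values(r1), _values(r2)
    if r1.shape != r2.shape:
        raise ValueError(f"shape mismatch: {r1.shape} vs {r2.shape}")
    return r1, r2


def residual_loss(model, recon1, recon2) -> float:
    """Symmetric residual loss: each artifact-subtracted reconstruction is
    pushed toward the *other* subset's reconstruction."""
    r1, r2 = _check_pair(recon1, recon2)
    e1 = r1 - _apply_g(model, r1) - r2
    e2 = r2 - _apply_g(model, r2) - r1
    return 0.5 * (float(np.mean(e1 ** 2)) + float(np.mean(e2 ** 2)))


def consistency_loss(model, recon1, recon2) -> float:
    """Regulariser: both artifact-subtracted reconstructions should agree."""
    r1, r2 = _check_pair(recon1, recon2)
    d = (r1 - _apply_g(model, r1)) - (r2 - _apply_g(model, r2))
    return float(np.mean(d ** 2))


def total_loss(model, recon1, recon2) -> float:
    return residual_loss(model, recon1, recon2) + consistency_loss(model, recon1, recon2)


def multi_subset_losses(model, recons) -> float:
    """Pairwise generalisation to >= 2 subset reconstructions: the average of
    residual + consistency loss over all unordered pairs.  With exactly two
    images this reduces to :func:`total_loss`."""
    recons = [_values(r) for r in recons]
    if len(recons) < 2:
        raise ValueError("need at least two reconstructions")
    pairs = [(i, j) for i in range(len(recons)) for j in range(i + 1, len(recons))]
    return float(np.mean([total_loss(model, recons[i], recons[j]) for i, j in pairs]))


# ---------------------------------------------------------------------------
# training


@dataclasses.dataclass(frozen=True)
class LossBreakdown:
    """Per-iteration records of (total, residual, consistency) loss."""

    total: np.ndarray
    residual: np.ndarray
    consistency: np.ndarray

    def __post_init__(self):
        t, r, c = (np.asarray(a, dtype=float) for a in
                   (self.total, self.residual, self.consistency))
        if not (len(t) == len(r) == len(c)):
            raise ValueError("loss records must have equal length")
        object.__setattr__(self, "total", t)
        object.__setattr__(self, "residual", r)
        object.__setattr__(self, "consistency", c)

    def __len__(self) -> int:
        return len(self.total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"iteration": np.arange(len(self)),
                             "total": self.total, "residual": self.residual,
                             "consistency": self.consistency})

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite; carries the history so far."""

    def __init__(self, message: str, history: LossBreakdown):
        super().__init__(message)
        self.history = history


class ZSA2A:
    """Zero-shot artifact-removal model for one image (slice).

    Parameters
    ----------
    recon1, recon2 : 2-D arrays or ReconImage
        Reconstructions of two independent random detector subsets of the
        same channel data.
    *extra
        Optional further subset reconstructions (>= 3-subset variant; the
        loss becomes the pairwise average).
    config : TrainConfig
    """

    def __init__(self, recon1, recon2, *extra, config: TrainConfig | None = None):
        self.config = config or TrainConfig()
        imgs = [_values(r) for r in (recon1, recon2, *extra)]
        shape = imgs[0].shape
        for im in imgs:
            if im.shape != shape:
                raise ValueError("all subset reconstructions must share a shape")
            if im.ndim != 2:
                raise ValueError("ZSA2A trains on 2-D images; use "
                                 "run_zsa2a_slicewise for volumes")
            if not np.all(np.isfinite(im)):
                raise ValueError("inputs must be finite")
        if len(imgs) != self.config.n_subsets:
            # keep the config honest if the caller passed extra images
            self.config = self.config.replace(n_subsets=len(imgs))
        self.images = imgs

    @classmethod
    def from_subsets(cls, channel_data, array, grid, subsets, *, c=None,
                     config: TrainConfig | None = None):
        """Build the model directly from sparse channel data and drawn subsets,
        reconstructing each subset with UBP."""
        from .forward import SPEED_OF_SOUND, restrict_channels
        from .recon import ubp_backproject
        c = SPEED_OF_SOUND if c is None else c
        recons = []
        for k, sub in enumerate(subsets):
            sub_data = restrict_channels(channel_data, sub)
            sub_array = type(array)(array.positions[np.asarray(sub.indices)],
                                    array.radius, array.coverage)
            recons.append(ubp_backproject(sub_data, sub_array, grid, c,
                                          provenance=f"subset{min(k + 1, 2)}"))
        slices = [r.values for r in recons]
        return cls(*slices, config=config)

    def fit(self) -> "ZSA2AResults":
        """Minimise the total loss by Adam with step-decayed learning rate."""
        cfg = self.config
        k = len(self.images)
        scale = 1.0
        if cfg.normalize:
            scale = max(float(np.abs(im).max()) for im in self.images) or 1.0
        x = np.stack([im / scale for im in self.images]).astype(np.float32)
        P = float(x[0].size)
        n_pairs = k * (k - 1) // 2
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]

        net = TinyConvNet(cfg.hidden_channels, cfg.negative_slope, seed=cfg.seed)
        opt = Adam(net.params, lr=cfg.lr)
        hist = np.empty((cfg.iterations, 3))
        # overflow during a diverging run is detected and reported, not warned
        static: dict = {}  # input-dependent precomputations, x is fixed
        with np.errstate(over="ignore", invalid="ignore"):
            for it in range(cfg.iterations):
                opt.lr = step_lr(cfg.lr, it, cfg.step_size, cfg.gamma)
                cache: dict = {}
                g = net.forward(x, cache, static=static)
                dg = np.zeros_like(g)
                l_res = 0.0
                l_cons = 0.0
                for i, j in pairs:
                    e_ij = x[i] - g[i] - x[j]
                    e_ji = x[j] - g[j] - x[i]
                    d_ij = (x[i] - g[i]) - (x[j] - g[j])
                    l_res += 0.5 * (float(np.mean(e_ij ** 2))
                                    + float(np.mean(e_ji ** 2)))
                    l_cons += float(np.mean(d_ij ** 2))
                    dg[i] -= (e_ij + 2.0 * d_ij) / P
                    dg[j] -= (e_ji - 2.0 * d_ij) / P
                l_res /= n_pairs
                l_cons /= n_pairs
                dg /= n_pairs
                hist[it] = (l_res + l_cons, l_res, l_cons)
                if not np.isfinite(hist[it, 0]):
                    raise TrainingDivergedError(
                        f"loss became non-finite at iteration {it}",
                        LossBreakdown(hist[:it, 0], hist[:it, 1], hist[:it, 2]))
                opt.step(net.backward(cache, dg))
        losses = LossBreakdown(hist[:, 0], hist[:, 1], hist[:, 2])
        return ZSA2AResults(self, ArtifactPredictor(net, scale), losses)


class ZSA2AResults:
    """Fitted artifact model: final parameters, loss history, diagnostics."""

    def __init__(self, model: ZSA2A, predictor: ArtifactPredictor,
                 losses: LossBreakdown):
        self.model = model
        self.predictor = predictor
        self.losses = losses

    def predict(self, image) -> np.ndarray:
        """Artifact estimate g(image)."""
        return self.predictor.predict(image)

    def decompose(self, recon0) -> "DecompositionResult":
        """Split ``recon0`` into clean + artifact (exactly conservative)."""
        return decompose(recon0, self.predictor)

    def summary(self) -> str:
        cfg = self.model.config
        buf = io.StringIO()
        w = buf.write
        w("Zero-shot artifact removal — fit summary\n")
        w("=" * 46 + "\n")
        w(f"{'subset reconstructions':<30}{len(self.model.images):>16}\n")
        w(f"{'image shape':<30}{str(self.model.images[0].shape):>16}\n")
        w(f"{'network parameters':<30}{self.predictor.parameter_count:>16}\n")
        w(f"{'hidden channels':<30}{cfg.hidden_channels:>16}\n")
        w(f"{'iterations':<30}{cfg.iterations:>16}\n")
        w(f"{'lr / step / gamma':<30}"
          f"{f'{cfg.lr:g} / {cfg.step_size} / {cfg.gamma:g}':>16}\n")
        w(f"{'seed':<30}{cfg.seed:>16}\n")
        w("-" * 46 + "\n")
        w(f"{'initial total loss':<30}{self.losses.total[0]:>16.6g}\n")
        w(f"{'final total loss':<30}{self.losses.total[-1]:>16.6g}\n")
        w(f"{'final residual loss':<30}{self.losses.residual[-1]:>16.6g}\n")
        w(f"{'final consistency loss':<30}{self.losses.consistency[-1]:>16.6g}\n")
        return buf.getvalue()

    def plot_losses(self, ax=None):
        """Loss-history curves on a log scale (matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        f = self.losses.to_frame()
        for col in ("total", "residual", "consistency"):
            ax.semilogy(f["iteration"], f[col], label=col)
        ax.set_xlabel("iteration")
        ax.set_ylabel("loss")
        ax.legend()
        return ax


def fit(recon_pair, config: TrainConfig | None = None):
    """Functional wrapper: ``fit((recon1, recon2), config)`` returns
    ``(ArtifactPredictor, LossBreakdown)``."""
    res = ZSA2A(*recon_pair, config=config).fit()
    return res.predictor, res.losses


# ---------------------------------------------------------------------------
# decomposition


@dataclasses.dataclass(frozen=True)
class DecompositionResult:
    """An exactly conservative split of ``source`` into clean + artifact.

    Conservation is enforced by construction: ``artifact`` is stored as the
    floating-point difference ``source - clean``, so
    ``source - clean == artifact`` holds bitwise at every pixel, and
    ``clean + artifact`` agrees with ``source`` to the last rounding of that
    addition (IEEE arithmetic cannot make the *re-addition* bitwise exact for
    every pixel whenever the artifact magnitude exceeds the source's).
    """

    clean: ReconImage
    artifact: ReconImage
    source: ReconImage

    def __post_init__(self):
        if not (self.clean.shape == self.artifact.shape == self.source.shape):
            raise ValueError("clean/artifact/source shapes must match")

    def conservation_error(self) -> float:
        """max |source - clean - artifact| — zero by construction."""
        return float(np.abs(self.source.values - self.clean.values
                            - self.artifact.values).max())


def _exact_split(a: np.ndarray, g: np.ndarray):
    """(clean, artifact) with artifact == a - clean bitwise."""
    clean = a - g
    artifact = a - clean
    return clean, artifact


def decompose(recon0, model) -> DecompositionResult:
    """Apply the trained predictor: artifact = g(recon0), clean = recon0 - artifact."""
    src_img = recon0 if isinstance(recon0, ReconImage) else ReconImage(np.asarray(recon0, dtype=float))
    a = src_img.values
    g = _apply_g(model, a)
    if g.shape != a.shape:
        raise ValueError("prediction shape does not match recon0")
    clean, artifact = _exact_split(a, g)
    grid = src_img.grid_ref
    return DecompositionResult(ReconImage(clean, grid), ReconImage(artifact, grid),
                               src_img)


# ---------------------------------------------------------------------------
# slice-wise 3-D driver


def run_zsa2a_slicewise(volume0: ReconImage, volume1: ReconImage,
                        volume2: ReconImage, axis: str = "z",
                        config: TrainConfig | None = None,
                        extra_volumes=(), return_losses: bool = False):
    """Clean a 3-D volume slice by slice.

    For every slice along ``axis`` a *fresh* network is trained on the
    corresponding (volume1, volume2) slice pair — identical hyperparameters,
    per-slice seeds derived deterministically from ``config.seed`` — and
    applied to the volume0 slice.  Outputs are restacked; conservation holds
    per slice and therefore for the volume.
    """
    config = config or TrainConfig()
    vols = [volume0, volume1, volume2, *extra_volumes]
    shape = vols[0].shape
    for v in vols:
        if v.ndim != 3:
            raise ValueError("run_zsa2a_slicewise expects 3-D volumes")
        if v.shape != shape:
            raise ValueError("all volumes must share the grid")
        if (v.grid_ref is not None and vols[0].grid_ref is not None
                and v.grid_ref != vols[0].grid_ref):
            raise ValueError("all volumes must share the grid")
    per_vol_slices = [extract_slices(v, axis) for v in vols]
    clean_slices, artifact_slices, histories = [], [], []
    for k in range(len(per_vol_slices[0])):
        s0 = per_vol_slices[0][k]
        train_imgs = [per_vol_slices[j][k] for j in range(1, len(vols))]
        slice_seed = int(np.random.SeedSequence(config.seed, spawn_key=(k,))
                         .generate_state(1)[0] & 0x7FFFFFFF)
        res = ZSA2A(*train_imgs, config=config.replace(seed=slice_seed)).fit()
        dec = res.decompose(s0)
        clean_slices.append(dec.clean)
        artifact_slices.append(dec.artifact)
        histories.append(res.losses)
    grid = volume0.grid_ref
    out = DecompositionResult(
        restack(clean_slices, axis, grid, volume0.provenance),
        restack(artifact_slices, axis, grid, volume0.provenance),
        volume0)
    return (out, histories) if return_losses else out
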