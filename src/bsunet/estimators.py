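"""Scikit-learn style estimator for the segmentation network family.

``DiscSegmenter`` wraps network construction, (two-stage) training and
thresholded prediction behind the familiar ``fit`` / ``predict`` /
``predict_proba`` interface, so the four variants compose with sklearn
model selection.  Inputs are stacks of 2-D grayscale images ``X`` of shape
``(n, H, W)`` with values in [0, 1] and binary masks ``y`` of the same
shape.
"""
from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .architectures import (CASCADE_VARIANTS, NetworkConfig, TensorShape,
                            build_network, summarize_network)
from .errors import ConfigError
from .nn import Adam, Tensor, bce_loss

__all__ = ["DiscSegmenter", "SMALL_PRESET", "PAPER_PRESET"]

#: Desk-scale preset: 64x64 phantoms, 1/8 channel widths, 50 epochs.
SMALL_PRESET = dict(image_size=64, width_multiplier=0.125, epochs=50,
                    batch_size=4)
#: Full-scale settings from the published recipe (GPU territory).
PAPER_PRESET = dict(image_size=256, width_multiplier=1.0, epochs=200,
                    batch_size=4)


class DiscSegmenter(BaseEstimator):
    """Binary disc segmentation with any of the four network variants.

    Parameters
    ----------
    variant : {"unet", "dilated_unet", "cascaded_unet", "bsu_net"}
    image_size : input matrix size (must be divisible by 2**depth).
    width_multiplier : channel-width scale in (0, 1]; 1 is the reference.
    learning_rate, epochs, batch_size : Adam / loop settings.
    binarize_threshold : probability cut for ``predict``.
    front_end_guidance : cascade ablation — inject the stage-1 map at the
        encoder input instead of the back-end (negative control).
    random_state : seeds weight init and batch shuffling.

    Attributes
    ----------
    network_ : the fitted second-stage (or only) network.
    stage1_ : the frozen conventional U-net for cascade variants, else None.
    loss_curve_ : per-epoch mean training loss.
    config_ : the resolved NetworkConfig.
    """

    def __init__(self, variant="unet", image_size=256, width_multiplier=1.0,
                 learning_rate=1e-3, epochs=200, batch_size=4,
                 binarize_threshold=0.5, front_end_guidance=False,
                 random_state=0, verbose=0):
        self.variant = variant
        self.image_size = image_size
        self.width_multiplier = width_multiplier
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.binarize_threshold = binarize_threshold
        self.front_end_guidance = front_end_guidance
        self.random_state = random_state
        self.verbose = verbose

    # -- helpers -----------------------------------------------------------
    def _make_config(self) -> NetworkConfig:
        kw = dict(variant=self.variant,
                  input_shape=TensorShape(self.image_size, self.image_size, 1),
                  width_multiplier=self.width_multiplier,
                  front_end_guidance=self.front_end_guidance)
        if self.variant in CASCADE_VARIANTS:
            kw["cascade_source"] = "unet"
        return NetworkConfig(**kw)

    @staticmethod
    def _check_Xy(X, y=None):
        X = np.asarray(X, np.float32)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ConfigError(f"X must be (n, H, W), got {X.shape}")
        if y is not None:
            y = np.asarray(y)
            if y.shape != X.shape:
                raise ConfigError(f"y shape {y.shape} != X shape {X.shape}")
            y = (y > 0.5).astype(np.float32)
        return X, y

    def _train_network(self, net, X, y, guide, rng):
        """Adam/BCE loop; returns per-epoch mean losses."""
        n = len(X)
        opt = Adam(net.parameters(), lr=self.learning_rate)
        losses = []
        net.train()
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = Tensor(X[idx][:, None])
                gb = None if guide is None else Tensor(guide[idx][:, None])
                prob = net.forward(xb, gb) if net.expects_guide or gb is not None \
                    else net.forward(xb)
                loss = bce_loss(prob, y[idx][:, None])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {_epoch}: {float(loss.data)}")
                net.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            losses.append(epoch_loss / n)
            if self.verbose and (_epoch % 10 == 0 or _epoch == self.epochs - 1):
                print(f"epoch {_epoch:4d}  loss {losses[-1]:.4f}")
        return losses

    # -- sklearn interface -------------------------------------------------
    def fit(self, X, y, stage1: "DiscSegmenter | None" = None):
        """Train on images X and masks y.

        For cascade variants, ``stage1`` may supply an already fitted
        conventional U-net; otherwise one is trained first with identical
        hyperparameters, then frozen while the second stage learns from its
        probability maps.
        """
        X, y = self._check_Xy(X, y)
        if len(X) == 0:
            raise ConfigError("empty training set")
        self.config_ = self._make_config()
        rng = np.random.default_rng(self.random_state)

        guide = None
        self.stage1_ = None
        if self.variant in CASCADE_VARIANTS:
            if stage1 is None:
                stage1 = DiscSegmenter(
                    variant="unet", image_size=self.image_size,
                    width_multiplier=self.width_multiplier,
                    learning_rate=self.learning_rate, epochs=self.epochs,
                    batch_size=self.batch_size,
                    binarize_threshold=self.binarize_threshold,
                    random_state=self.random_state, verbose=self.verbose)
                stage1.fit(X, y)
            elif not hasattr(stage1, "network_"):
                raise ConfigError("stage1 estimator is not fitted")
            self.stage1_ = stage1
            guide = self.stage1_.predict_proba(X)

        self.network_ = build_network(self.config_, seed=self.random_state)
        self.loss_curve_ = self._train_network(self.network_, X, y, guide, rng)
        self.network_.eval()
        self.summary_ = summarize_network(self.config_)
        return self

    def predict_proba(self, X, batch_size: int = 8) -> np.ndarray:
        """Per-pixel foreground probabilities, shape (n, H, W)."""
        if not hasattr(self, "network_"):
            raise ConfigError("estimator is not fitted")
        X, _ = self._check_Xy(X)
        guide = self.stage1_.predict_proba(X) if self.stage1_ is not None else None
        self.network_.eval()
        out = []
        for start in range(0, len(X), batch_size):
            xb = X[start:start + batch_size][:, None]
            gb = None if guide is None else guide[start:start + batch_size][:, None]
            prob = self.network_.predict_proba(xb, gb) if gb is not None \
                else self.network_.predict_proba(xb)
            out.append(prob[:, 0])
        return np.concatenate(out)

    def predict(self, X) -> np.ndarray:
        """Binary masks at the configured threshold."""
        return (self.predict_proba(X) > self.binarize_threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean whole-area Dice over cases."""
        from .metrics import dice
        pred = self.predict(X)
        y = np.asarray(y)
        return float(np.mean([dice(p, t) for p, t in zip(pred, y)]))

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint: weights (and frozen stage-1 weights) as npz plus the
        producing parameters."""
        import json
        from pathlib import Path
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"net.{k}": v for k, v in self.network_.state_arrays()}
        if self.stage1_ is not None:
            arrays.update({f"stage1.{k}": v
                           for k, v in self.stage1_.network_.state_arrays()})
        np.savez_compressed(path, **arrays)
        sidecar = {"params": self.get_params(),
                   "config": self.config_.to_dict(),
                   "loss_curve": list(map(float, self.loss_curve_))}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "DiscSegmenter":
        import json
        from pathlib import Path
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        est = cls(**sidecar["params"])
        est.config_ = est._make_config()
        est.network_ = build_network(est.config_, seed=est.random_state)
        with np.load(path) as z:
            est.network_.load_state_arrays(
                [(k[4:], z[k]) for k in z.files if k.startswith("net.")])
            est.stage1_ = None
            s1 = [(k[7:], z[k]) for k in z.files if k.startswith("stage1.")]
            if s1:
                est.stage1_ = cls(variant="unet", image_size=est.image_size,
                                  width_multiplier=est.width_multiplier,
                                  random_state=est.random_state)
                est.stage1_.config_ = est.stage1_._make_config()
                est.stage1_.network_ = build_network(est.stage1_.config_,
                                                     seed=est.random_state)
                est.stage1_.network_.load_state_arrays(s1)
                est.stage1_.stage1_ = None
                est.stage1_.loss_curve_ = []
                est.stage1_.network_.eval()
        est.loss_curve_ = sidecar.get("loss_curve", [])
        est.network_.eval()
        return est
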