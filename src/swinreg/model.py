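"""Model/Results interface to the registration stack.

:class:`AffineRegistration` bundles the data (an atlas and moving images, or
ready-made pairs) with the architecture and training configuration;
:meth:`AffineRegistration.fit` runs the unsupervised optimisation and returns
an :class:`AffineRegistrationResults` carrying the trained network, the loss
trajectory, per-pair transform estimates, diagnostics and a ``summary()``
table.  Simulation (``swinreg.synthetic``) and plotting hang off these two
objects; the command-line interface is a thin shell over them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import AffineTransform, GeometricParams, decompose_affine
from .metrics import EvalReport, evaluate
from .network import MultiStageAffineNetwork, NetworkConfig
from .training import TrainConfig, TrainResult, train, validation_similarity
from .warp import warp_timeseries, warp_volume


class AffineRegistration:
    """Unsupervised affine registration model.

    Parameters
    ----------
    pairs
        Iterable of objects with ``fixed`` and ``moving`` arrays (identical
        shapes, intensities in [0, 1]); ``swinreg.synthetic`` pairs qualify.
    network_config, train_config
        Architecture and optimisation settings; defaults follow the reference
        configuration (embed width 64, depths (1, 2, 2), Adam at 1e-4,
        batch 1, lambda 0.01).
    """

    def __init__(self, pairs, network_config: NetworkConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.pairs = list(pairs)
        self.network_config = network_config or NetworkConfig()
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_cohort(cls, cohort, network_config=None, train_config=None) -> "AffineRegistration":
        return cls(cohort.pairs, network_config=network_config, train_config=train_config)

    def fit(self, val_pairs=None) -> "AffineRegistrationResults":
        network = MultiStageAffineNetwork(self.network_config, seed=self.train_config.seed)
        result = train(self.pairs, self.train_config, network=network, val_pairs=val_pairs)
        return AffineRegistrationResults(self, result)


@dataclass
class AffineRegistrationResults:
    model: AffineRegistration
    fit_result: TrainResult

    @property
    def network(self) -> MultiStageAffineNetwork:
        return self.fit_result.network

    @property
    def history(self) -> pd.DataFrame:
        return self.fit_result.history

    # -- estimation -----------------------------------------------------------
    def transform(self, fixed: np.ndarray, moving: np.ndarray) -> AffineTransform:
        """Estimated sampling transform aligning ``moving`` to ``fixed``."""
        return self.network.register(fixed, moving).transform

    def params(self, fixed: np.ndarray, moving: np.ndarray) -> GeometricParams:
        """The estimate decomposed into [t, r, s, h] (pivot at the origin)."""
        return decompose_affine(self.transform(fixed, moving))

    def register_volume(self, fixed: np.ndarray, moving: np.ndarray) -> np.ndarray:
        return warp_volume(moving, self.transform(fixed, moving))

    def register_series(self, fixed: np.ndarray, series: np.ndarray) -> np.ndarray:
        """4-D protocol: estimate once from the temporal mean, then apply the
        single matrix to every frame."""
        from .io import temporal_mean

        mean3d = temporal_mean(series)
        return warp_timeseries(series, self.transform(fixed, mean3d))

    # -- diagnostics ----------------------------------------------------------
    def validation_loss(self, pairs) -> float:
        return validation_similarity(self.network, pairs,
                                     self.model.train_config.ncc_window)

    def evaluate(self, pairs, spacing=None) -> tuple[EvalReport, list[EvalReport]]:
        """Label-overlap evaluation (DSC, DSC30, HD95) on pairs that carry
        ``fixed_labels``/``moving_labels``."""
        return evaluate(self.network, pairs, spacing=spacing)

    def summary(self, eval_report: EvalReport | None = None) -> str:
        cfg = self.model.network_config
        tcfg = self.model.train_config
        n_params = sum(p.data.size for p in self.network.parameters())
        lines = [
            "Affine registration results",
            "=" * 46,
            f"{'stages':<28}{cfg.levels}",
            f"{'embed width C':<28}{cfg.embed_dim}",
            f"{'block pairs per stage':<28}{cfg.depths}",
            f"{'patch/attention windows':<28}{cfg.patch_windows}",
            f"{'attention heads':<28}{cfg.heads}",
            f"{'trainable parameters':<28}{n_params}",
            f"{'training pairs':<28}{len(self.model.pairs)}",
            f"{'iterations':<28}{self.fit_result.iterations}",
            f"{'learning rate':<28}{tcfg.learning_rate}",
            f"{'lambda (regularization)':<28}{tcfg.lam}",
            f"{'best validation sim loss':<28}{self.fit_result.best_val:.4f}",
        ]
        if len(self.history):
            lines.append(f"{'final training loss':<28}{self.history['total'].iloc[-1]:.4f}")
        if eval_report is not None:
            s = eval_report.summary()
            lines += [
                "-" * 46,
                f"{'mean DSC (registered)':<28}{s['mean_dsc']:.4f}",
                f"{'mean DSC (unregistered)':<28}{s['mean_dsc_unregistered']:.4f}",
                f"{'DSC30':<28}{s['dsc30']:.4f}",
                f"{'mean HD95 (voxels)':<28}{s['mean_hd95']:.4f}",
            ]
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Training-loss trajectory (total and similarity terms)."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        h = self.history
        ax.plot(h["iteration"], h["total"], label="total", lw=1)
        ax.plot(h["iteration"], h["sim"], label="similarity", lw=1, alpha=0.7)
        ax.set_xlabel("iteration")
        ax.set_ylabel("loss")
        ax.legend()
        return ax

    # -- persistence ----------------------------------------------------------
    def save(self, weight_path, sidecar_path) -> None:
        self.network.save(weight_path, sidecar_path)
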