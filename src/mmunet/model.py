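"""Model/Results facade over the network, loss and training loop.

Follows the fitted-model idiom: :class:`MMUNet` is constructed from a
slice dataset plus configuration, ``fit()`` runs the seeded optimization
and returns a :class:`FitResults` carrying the trained network, the loss
history, evaluation helpers and a ``summary()`` table.

Example
-------
>>> from mmunet import MMUNet, phantom, brats_io
>>> cases = phantom.generate_dataset(8, seed=7)
>>> slices = [brats_io.SlicePair(brats_io.normalize(c.images), c.labels, c.case_id)
...           for c in cases]
>>> model = MMUNet(slices, variant="full", base_channels=8, input_size=160)
>>> results = model.fit(max_steps=50)          # doctest: +SKIP
>>> print(results.summary())                   # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .brats_io import SlicePair
from .losses import LossConfig
from .metrics import EvalRecord, aggregate
from .network import MMUNetNetwork, NetworkConfig, build, make_variant
from .training import TrainConfig, TrainResult, evaluate, train


class MMUNet:
    """A multimodal segmentation model bound to a training dataset.

    Parameters
    ----------
    dataset : list of SlicePair
        Normalized four-modality slices with dense labels {0,1,2,3}.
    variant : str
        Named architecture variant ("full", "baseline", ...).
    loss : LossConfig, optional
        Compound-loss weights; defaults to Dice 0.1 + focal 0.9.
    **config_overrides
        Any :class:`NetworkConfig` field (base_channels, input_size, ...).
    """

    def __init__(
        self,
        dataset: list[SlicePair],
        *,
        variant: str = "full",
        loss: LossConfig | None = None,
        config: NetworkConfig | None = None,
        **config_overrides,
    ):
        if not dataset:
            raise ValueError("dataset must be nonempty")
        if config is None:
            # an explicit input_size override wins over the inferred slice size
            config_overrides.setdefault("input_size", dataset[0].images.shape[-1])
            config = make_variant(variant, **config_overrides)
        for pair in dataset:
            if pair.images.shape != (config.modalities, config.input_size, config.input_size):
                raise ValueError(
                    f"slice {pair.case_id}#{pair.slice_index} has shape {pair.images.shape}, "
                    f"expected {(config.modalities, config.input_size, config.input_size)}"
                )
        self.dataset = list(dataset)
        self.config = config
        self.loss_config = loss or LossConfig()

    @classmethod
    def from_directory(cls, directory, *, policy: str = "tumor-bearing", **kwargs) -> "MMUNet":
        """Build from a BraTS-layout directory via the I/O pipeline."""
        from .brats_io import load_dataset

        return cls(load_dataset(directory, policy), **kwargs)

    def fit(
        self,
        train_config: TrainConfig | None = None,
        **overrides,
    ) -> "FitResults":
        """Run the seeded training loop and return the results object."""
        cfg = train_config or TrainConfig(loss=self.loss_config)
        if overrides:
            cfg = replace(cfg, **overrides)
        net = build(self.config)
        history = train(net, self.dataset, cfg)
        return FitResults(self, net, cfg, history)


class FitResults:
    """The outcome of :meth:`MMUNet.fit`: trained weights plus diagnostics."""

    def __init__(self, model: MMUNet, network: MMUNetNetwork, train_config: TrainConfig,
                 history: TrainResult):
        self.model = model
        self.network = network
        self.train_config = train_config
        self.history = history

    @property
    def loss_history(self) -> list[float]:
        return self.history.step_losses

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Label maps for a (N, 4, H, W) batch."""
        return self.network.predict_labels(images)

    def evaluate(self, dataset: list[SlicePair] | None = None) -> list[EvalRecord]:
        return evaluate(self.network, dataset or self.model.dataset)

    def score(self, dataset: list[SlicePair] | None = None) -> dict:
        """Aggregate evaluation summary (per-region and overall means)."""
        return aggregate(self.evaluate(dataset))

    def save(self, path) -> None:
        self.network.save_weights(path)

    def summary(self) -> str:
        s = self.score()
        lines = [
            "MM-UNet fit results",
            "===================",
            f"variant config       hab={self.network.config.hab_enabled} "
            f"({self.network.config.hab_order}), dcb={self.network.config.dcb_enabled} "
            f"({self.network.config.dcb_position})",
            f"parameters           {self.network.count_parameters():,}",
            f"training slices      {len(self.model.dataset)}",
            f"steps / epochs       {self.history.steps} / {len(self.history.epoch_losses)}",
            f"loss (first -> last) {self.history.step_losses[0]:.4f} -> "
            f"{self.history.step_losses[-1]:.4f}",
        ]
        for region, vals in s["per_region"].items():
            hd = "n/a" if vals["hd95_mean"] is None else f"{vals['hd95_mean']:.3f}"
            ds = "n/a" if vals["dsc_mean"] is None else f"{vals['dsc_mean']:.3f}"
            lines.append(f"train DSC/HD95 {region}   {ds} / {hd}")
        if s["mean_dsc"] is not None:
            lines.append(f"mean train DSC       {s['mean_dsc']:.3f}")
        return "\n".join(lines)
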