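"""Model/Results front end.

:class:`DCCLNet` binds a split dataset to a run configuration; ``fit()``
trains the full semi-supervised framework (or any ablation of it) and
returns a :class:`DCCLNetResults` carrying the best backbone weights,
the per-iteration loss log, validation history, held-out test metrics
and a ``summary()`` table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import trainer as _trainer
from .metrics import MetricReport
from .phantom import SplitDataset, read_fixture
from .trainer import RunConfig, TrainedRun


class DCCLNet:
    """Deep consistent collaborative learning segmentation model.

    Parameters
    ----------
    data:
        A :class:`~dcclnet.phantom.SplitDataset` with labeled/unlabeled
        train pools and labeled val/test partitions.
    config:
        Run configuration; defaults reproduce the full framework
        (auxiliary decoders + mean teacher + transformer co-training).
    """

    def __init__(self, data: SplitDataset, config: RunConfig | None = None):
        self.data = data
        self.config = config or RunConfig(n_classes=data.n_classes)
        if self.config.n_classes != data.n_classes:
            raise _trainer.ConfigError(
                f"config n_classes {self.config.n_classes} != dataset "
                f"{data.n_classes}")

    @classmethod
    def from_fixture(cls, path, config: RunConfig | None = None) -> "DCCLNet":
        return cls(read_fixture(path), config)

    def fit(self, progress: bool = False, resume_from=None) -> "DCCLNetResults":
        run = _trainer.fit(self.config, self.data, progress=progress,
                           resume_from=resume_from)
        return DCCLNetResults(self, run)


class DCCLNetResults:
    """Fitted-run record: best checkpoint, logs and held-out metrics."""

    def __init__(self, model: DCCLNet, run: TrainedRun):
        self.model = model
        self.run = run
        self._backbone = None

    # -- convenience accessors ----------------------------------------
    @property
    def best_iteration(self) -> int:
        return self.run.best_iteration

    @property
    def best_val_dsc(self) -> float:
        return self.run.best_val_dsc

    @property
    def test_metrics(self) -> MetricReport:
        return self.run.test_report

    @property
    def log(self) -> pd.DataFrame:
        return pd.DataFrame(self.run.log)

    @property
    def val_history(self) -> pd.DataFrame:
        return pd.DataFrame(self.run.val_history, columns=["iteration", "val_dsc"])

    def backbone(self):
        if self._backbone is None:
            self._backbone = self.run.best_backbone()
        return self._backbone

    def predict(self, images) -> np.ndarray:
        """Argmax label maps from the best backbone."""
        return _trainer.predict(self.backbone(), images)

    def evaluate(self, split: str = "test") -> MetricReport:
        pairs = getattr(self.model.data, split)
        return _trainer.evaluate_pairs(self.backbone(), pairs,
                                       self.model.config.n_classes)

    def summary(self) -> str:
        cfg = self.model.config
        rep = self.test_metrics
        lines = [
            "Deep Consistent Collaborative Learning — training summary",
            "=" * 60,
            f"components:        {cfg.components.tag()}",
            f"iterations:        {cfg.total_iters}",
            f"labeled / unlabeled images: "
            f"{len(self.model.data.labeled)} / {len(self.model.data.unlabeled)}",
            f"best iteration:    {self.best_iteration}",
            f"best val DSC:      {self.best_val_dsc:.4f}",
            "",
            "test metrics (foreground classes):",
            rep.to_table(),
        ]
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Write the run artifacts (log CSV, metrics JSON, best weights)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.log.to_csv(out / "training_log.csv", index=False)
        import json

        with open(out / "metrics.json", "w") as f:
            json.dump({"best_iteration": self.best_iteration,
                       "best_val_dsc": self.best_val_dsc,
                       "test": self.test_metrics.to_dict()}, f, indent=2)
        np.savez(out / "best_backbone.npz", **self.run.best_state)
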