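"""Quick-look plots for features and training runs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from chickcall.features import FeatureMatrix
from chickcall.nn.training import TrainHistory


def plot_feature(feature: FeatureMatrix, sample_rate: int = 48_000, hop: int = 128, ax=None):
    """Heat map of a call's feature matrix (time on x)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    values = feature.values.T
    extent = [0, feature.values.shape[0] * hop / sample_rate, 0, values.shape[0]]
    ax.imshow(values, origin="lower", aspect="auto", extent=extent, cmap="magma")
    ax.set_xlabel("time (s)")
    ax.set_ylabel({"spectrogram": "frequency bin",
                   "cepstrogram": "cepstral coefficient",
                   "mfcc_logfbank": "feature index"}[feature.kind])
    ax.set_title(feature.kind)
    return ax


def plot_history(history: TrainHistory, ax=None):
    """Training/validation curves with the best epoch marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    epochs = np.arange(1, len(history.train_loss) + 1)
    ax.plot(epochs, history.train_accuracy, label="train accuracy")
    ax.plot(epochs, history.val_accuracy, label="validation accuracy")
    ax.axvline(history.best_epoch, ls="--", c="gray", lw=1, label="best epoch")
    ax.set_xlabel("epoch")
    ax.set_ylabel("accuracy")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="lower right", fontsize=8)
    return ax
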