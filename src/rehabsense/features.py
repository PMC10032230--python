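"""Per-channel engineered statistics and train-fitted standardization.

Ten statistics are computed independently for each of the six sensor
channels of a window (60 features total): median, RMS (absolute energy),
standard deviation, variance, minimum, maximum, skewness, excess kurtosis,
mean spectral energy, and mean crossings.

Conventions (population moments, denominator L):

* skewness = m3 / m2^1.5 and excess kurtosis = m4 / m2^2 − 3, both defined
  as 0 for a constant channel (m2 = 0) so constant windows never produce
  NaN;
* mean spectral energy = mean over all L DFT bins of |X_k|², DC bin
  included, which by Parseval equals L · mean(x²);
* mean crossings counts consecutive sample pairs whose deviations from the
  channel mean have strictly opposite signs (a sample exactly at the mean
  is not a crossing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FEATURE_NAMES = (
    "median",
    "rms",
    "std",
    "var",
    "min",
    "max",
    "skew",
    "kurtosis",
    "spectral_energy",
    "mean_crossings",
)

CHANNEL_NAMES = ("ax", "ay", "az", "gx", "gy", "gz")


def feature_columns() -> list[str]:
    """Column names in channel-major order, e.g. ax_median … gz_mean_crossings."""
    return [f"{ch}_{feat}" for ch in CHANNEL_NAMES for feat in FEATURE_NAMES]


def engineered_features(windows: np.ndarray) -> np.ndarray:
    """Compute the 60 engineered features for a batch of windows.

    Parameters
    ----------
    windows : (W, L, 6) or (L, 6) array
        Window tensor; a single window is promoted to a batch of one.

    Returns
    -------
    (W, 60) array, columns ordered as :func:`feature_columns`.
    """
    x = np.asarray(windows, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.ndim != 3 or x.shape[2] != 6:
        raise ValueError(f"expected (W, L, 6) windows, got shape {x.shape}")
    if x.shape[1] < 2:
        raise ValueError("window length must be >= 2")
    if not np.isfinite(x).all():
        bad = np.nonzero(~np.isfinite(x).all(axis=(0, 1)))[0]
        names = [CHANNEL_NAMES[c] for c in bad]
        raise ValueError(f"non-finite values in channel(s) {names}")

    L = x.shape[1]
    mean = x.mean(axis=1)  # (W, 6)
    dev = x - mean[:, None, :]
    m2 = (dev**2).mean(axis=1)
    m3 = (dev**3).mean(axis=1)
    m4 = (dev**4).mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(m2 > 0, m3 / np.where(m2 > 0, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(m2 > 0, m4 / np.where(m2 > 0, m2, 1.0) ** 2 - 3.0, 0.0)

    spectrum = np.abs(np.fft.fft(x, axis=1)) ** 2
    spectral_energy = spectrum.mean(axis=1)

    signs = np.sign(dev)
    crossings = (signs[:, :-1, :] * signs[:, 1:, :] < 0).sum(axis=1).astype(float)

    feats = np.stack(
        [
            np.median(x, axis=1),
            np.sqrt((x**2).mean(axis=1)),
            np.sqrt(m2),
            m2,
            x.min(axis=1),
            x.max(axis=1),
            skew,
            kurt,
            spectral_energy,
            crossings,
        ],
        axis=-1,
    )  # (W, 6, 10)
    out = feats.reshape(len(x), -1)
    return out[0] if single else out


@dataclass
class FeatureScaler:
    """Per-column z-score scaler fitted on training rows only.

    Zero-variance columns are mapped to 0 rather than dividing by zero, so
    a constant training column contributes nothing to any distance.
    """

    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mean_ is not None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) == 0:
            raise ValueError("scaler requires a non-empty 2-D training matrix")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, np.inf)  # constant column → 0 after scaling
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("scaler has not been fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


@dataclass
class FeatureMatrix:
    """Feature rows with column metadata and extractor provenance."""

    X: np.ndarray
    columns: list[str]
    extractor: str = "engineered"
    scaler: FeatureScaler | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError(
                f"X shape {self.X.shape} inconsistent with {len(self.columns)} columns"
            )
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite entries")

    def __len__(self) -> int:
        return len(self.X)
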