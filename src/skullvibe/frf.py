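"""Frequency response function (FRF) containers and CSV interchange.

An FRF here is a complex spectrum of acceleration per unit incident
acoustic pressure (m/s^2/Pa) on a strictly increasing frequency grid,
one spectrum per named sensor channel (e.g. ``S/ML``, ``L/AP``).

The CSV dialect used throughout the pipeline stores one row per
frequency: a ``frequency_Hz`` column followed by ``<channel>_re`` and
``<channel>_im`` column pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FRFSet:
    """Complex FRFs for a set of named channels on a shared grid.

    Parameters
    ----------
    freq : ndarray
        Frequency grid, Hz, strictly increasing.
    channels : dict[str, ndarray]
        Complex spectrum per channel name, same length as ``freq``.
    units : str
        Physical units of the spectra (default acceleration per unit
        pressure).
    """

    freq: np.ndarray
    channels: dict
    units: str = "m/s^2/Pa"

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.ndim != 1 or self.freq.size == 0:
            raise ValueError("frequency grid must be a nonempty 1-D array")
        if not np.all(np.diff(self.freq) > 0):
            raise ValueError("frequency grid must be strictly increasing")
        clean = {}
        for name, h in self.channels.items():
            h = np.asarray(h, dtype=complex)
            if h.shape != self.freq.shape:
                raise ValueError(
                    f"channel {name!r} has {h.shape[0] if h.ndim else 0} samples, "
                    f"grid has {self.freq.size}"
                )
            if not np.all(np.isfinite(h)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            clean[name] = h
        self.channels = clean

    @property
    def names(self) -> list:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def restrict(self, fmin: float, fmax: float) -> "FRFSet":
        """Restrict all channels to the closed band [fmin, fmax]."""
        keep = (self.freq >= fmin) & (self.freq <= fmax)
        if not keep.any():
            raise ValueError(f"no grid points in [{fmin}, {fmax}] Hz")
        return FRFSet(
            self.freq[keep],
            {k: v[keep] for k, v in self.channels.items()},
            self.units,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {"frequency_Hz": self.freq}
        for name, h in self.channels.items():
            cols[f"{name}_re"] = h.real
            cols[f"{name}_im"] = h.imag
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path, units: str = "m/s^2/Pa") -> "FRFSet":
        df = pd.read_csv(path)
        if "frequency_Hz" not in df.columns:
            raise ValueError(f"{path}: missing frequency_Hz column")
        channels = {}
        for col in df.columns:
            if col.endswith("_re"):
                name = col[:-3]
                im = f"{name}_im"
                if im not in df.columns:
                    raise ValueError(f"{path}: {col} has no matching {im}")
                channels[name] = df[col].to_numpy() + 1j * df[im].to_numpy()
        return cls(df["frequency_Hz"].to_numpy(), channels, units)


def default_sweep(fmin: float = 170.0, fmax: float = 1000.0, n: int = 416) -> np.ndarray:
    """The default frequency sweep: 416 points over 170-1000 Hz,
    matching the underwater measurement campaign the models are
    validated against."""
    return np.linspace(fmin, fmax, n)
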