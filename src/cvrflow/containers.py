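"""Core data containers shared by all analysis stages.

These are thin, validated wrappers around numpy arrays: an end-tidal gas
trace (:class:`PhysioTrace`), a BOLD time series that is either a regional
1D trace or a full 4D volume stack (:class:`BoldSeries`), and the set of
tissue/edema/brain masks on the functional grid (:class:`MaskVolume`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PhysioTrace", "BoldSeries", "MaskVolume", "MASK_LABELS"]


@dataclass(frozen=True)
class PhysioTrace:
    """End-tidal gas partial-pressure time series in mmHg.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing. Sampling may be
        nonuniform (breath-to-breath data).
    values
        Partial pressures in mmHg; finite and positive.
    gas
        ``"CO2"`` or ``"O2"``.
    """

    times: np.ndarray
    values: np.ndarray
    gas: str = "CO2"

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        v = np.atleast_1d(np.asarray(self.values, dtype=float))
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1D arrays of equal length")
        if t.size == 0:
            raise ValueError("empty trace")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("trace values must be finite and positive (mmHg)")
        if self.gas not in ("CO2", "O2"):
            raise ValueError(f"unknown gas {self.gas!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class BoldSeries:
    """BOLD signal: a regional 1D trace or a 4D ``(x, y, z, t)`` stack.

    Signal units are arbitrary. ``tr`` is the volume repetition time in
    seconds; volume ``k`` is acquired at ``k * tr``.
    """

    data: np.ndarray
    tr: float
    slice_axis: int = 2  # spatial axis along which slices were acquired

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim not in (1, 4):
            raise ValueError("BOLD data must be 1D (regional) or 4D (x, y, z, t)")
        if d.shape[-1] < 2:
            raise ValueError("need at least 2 volumes")
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        if d.ndim == 4 and self.slice_axis not in (0, 1, 2):
            raise ValueError("slice_axis must identify a spatial axis (0, 1, or 2)")
        object.__setattr__(self, "data", d)

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[-1])

    @property
    def is_regional(self) -> bool:
        return self.data.ndim == 1

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each volume in seconds (``k * tr``)."""
        return np.arange(self.n_volumes) * self.tr


MASK_LABELS = ("background", "brain", "gm", "wm", "csf", "edema")


@dataclass(frozen=True)
class MaskVolume:
    """Binary masks on the functional grid.

    GM/WM/CSF are subsets of the brain mask. The edema mask may overlap any
    tissue label and, after dilation, may extend outside the brain.
    ``background`` is derived as the complement of the brain mask.
    """

    brain: np.ndarray
    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    edema: np.ndarray
    voxel_dims: tuple[float, float, float] = (2.3, 2.3, 2.5)  # mm

    def __post_init__(self) -> None:
        arrays = {}
        shape = None
        for name in ("brain", "gm", "wm", "csf", "edema"):
            a = np.asarray(getattr(self, name), dtype=bool)
            if a.ndim != 3:
                raise ValueError(f"{name} mask must be 3D")
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise ValueError("all masks must share one grid")
            arrays[name] = a
        for name in ("gm", "wm", "csf"):
            if np.any(arrays[name] & ~arrays["brain"]):
                raise ValueError(f"{name} mask extends outside the brain mask")
        for name, a in arrays.items():
            object.__setattr__(self, name, a)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.brain.shape

    def get(self, label: str) -> np.ndarray:
        """Return the boolean mask for ``label`` (see ``MASK_LABELS``)."""
        if label == "background":
            return ~self.brain
        if label not in ("brain", "gm", "wm", "csf", "edema"):
            raise ValueError(f"unknown mask label {label!r}")
        return getattr(self, label)

    def with_label(self, label: str, mask: np.ndarray) -> "MaskVolume":
        """Return a copy with one label replaced."""
        if label not in ("brain", "gm", "wm", "csf", "edema"):
            raise ValueError(f"unknown mask label {label!r}")
        return replace(self, **{label: np.asarray(mask, dtype=bool)})
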