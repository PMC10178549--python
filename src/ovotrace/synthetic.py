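"""Synthetic three-class Vis/NIR transmission spectra.

Real duck-egg spectra behind published origin-classification results are not
publicly deposited, so this generator emulates their reported statistical
structure on a 400-1100 nm axis:

* a smooth transmission baseline (broad bell centred near 750 nm, where the
  shell/albumen window transmits most light);
* a class-dependent mean intensity level over 550-900 nm, ordered
  Jiangsu (1) > Henan (2) > Sichuan (0);
* two absorption dips near 700 and 800 nm (water/alcohol O-H overtone
  bands), modelled as negative Gaussians, whose 700:800 depth ratio is
  ordered Jiangsu > Henan > Sichuan;
* per-sample multiplicative scatter (slope) and additive offset, so MSC and
  SNV have realistic work to do, plus per-point Gaussian noise.

All magnitudes are the generator's own choices (no numeric spectra are
published); they are configurable, and chosen so that after scatter
correction the only class-discriminating structure is the pair of
absorption bands. With a fixed seed the output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ovotrace.core import SpectraTable
from ovotrace.errors import ValidationError

#: per-class totals mirroring the reference study population
#: (class 0 Sichuan, 1 Jiangsu, 2 Henan)
DEFAULT_N_PER_CLASS = (110, 130, 111)

#: per-class counts of the default train/test/online benchmark splits
DEFAULT_SPLIT_COUNTS = {
    "train": (56, 70, 56),
    "test": (24, 30, 25),
    "online": (30, 30, 30),
}


def default_grid() -> np.ndarray:
    """400-1100 nm at 0.5 nm: 1401 points, the instrument sampling interval."""
    return np.linspace(400.0, 1100.0, 1401)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic spectrum model.

    ``class_levels`` scales whole spectra per class; ``peak_ratio_by_class``
    sets the 700:800 nm dip-depth ratio per class. Both must respect the
    ordering class 1 > class 2 > class 0.
    """

    wavelength_grid: np.ndarray = field(default_factory=default_grid)
    class_levels: tuple[float, float, float] = (0.93, 1.07, 1.0)
    level_band_nm: tuple[float, float] = (550.0, 900.0)
    peak_centers_nm: tuple[float, float] = (700.0, 800.0)
    peak_widths_nm: tuple[float, float] = (25.0, 30.0)
    peak_ratio_by_class: tuple[float, float, float] = (0.5, 1.5, 1.0)
    peak_depth: float = 0.25
    baseline_center_nm: float = 750.0
    baseline_width_nm: float = 180.0
    baseline_floor: float = 0.15
    scatter_slope_range: tuple[float, float] = (0.85, 1.15)
    scatter_offset_sd: float = 0.02
    noise_sd: float = 0.01
    n_per_class: tuple[int, int, int] = DEFAULT_N_PER_CLASS
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelength_grid, dtype=float)
        if not np.all(np.diff(w) > 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "wavelength_grid", w)
        lv, rt = self.class_levels, self.peak_ratio_by_class
        if not (lv[1] > lv[2] > lv[0]):
            raise ValidationError(
                "class_levels must be ordered class1 > class2 > class0"
            )
        if not (rt[1] > rt[2] > rt[0]):
            raise ValidationError(
                "peak_ratio_by_class must be ordered class1 > class2 > class0"
            )
        if min(self.peak_widths_nm) <= 0 or self.peak_depth <= 0:
            raise ValidationError("peak widths and depth must be > 0")
        if self.scatter_offset_sd < 0 or self.noise_sd < 0:
            raise ValidationError("noise scales must be >= 0")
        lo, hi = self.scatter_slope_range
        if not 0 < lo <= hi:
            raise ValidationError("scatter_slope_range must satisfy 0 < lo <= hi")
        if min(self.n_per_class) < 1:
            raise ValidationError("n_per_class entries must be >= 1")


def class_template(config: GeneratorConfig, label: int) -> np.ndarray:
    """Noise-free spectrum of one class (baseline x level x absorption dips).

    The class-dependent level multiplier is confined to the 550-900 nm band
    (smooth sigmoid shoulders), where real origin differences in mean level
    are reported; outside the band the classes share the baseline and the
    only class signature is the pair of absorption dips.
    """
    w = config.wavelength_grid
    base = config.baseline_floor + (1 - config.baseline_floor) * np.exp(
        -0.5 * ((w - config.baseline_center_nm) / config.baseline_width_nm) ** 2
    )
    lo, hi = config.level_band_nm
    band = 1.0 / (1.0 + np.exp(-(w - lo) / 20.0)) / (1.0 + np.exp((w - hi) / 20.0))
    level = 1.0 + (config.class_levels[label] - 1.0) * band
    (c1, c2), (s1, s2) = config.peak_centers_nm, config.peak_widths_nm
    dip1 = np.exp(-0.5 * ((w - c1) / s1) ** 2)
    dip2 = np.exp(-0.5 * ((w - c2) / s2) ** 2)
    # the class ratio reallocates absorption between the two dips while the
    # total absorbed area stays fixed, so band means track class_levels and
    # the ratio signature lives only at the peaks
    ratio = config.peak_ratio_by_class[label]
    depth = config.peak_depth
    d2 = depth * (s1 + s2) / (ratio * s1 + s2)
    d1 = ratio * d2
    absorption = 1.0 - d1 * dip1 - d2 * dip2
    return level * base * absorption


def generate(config: GeneratorConfig | None = None) -> SpectraTable:
    """Draw a labelled spectra table from the generator model."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    w = config.wavelength_grid
    rows, labels, ids = [], [], []
    for label, n in enumerate(config.n_per_class):
        template = class_template(config, label)
        lo, hi = config.scatter_slope_range
        slopes = rng.uniform(lo, hi, size=n)
        offsets = rng.normal(0.0, config.scatter_offset_sd, size=n)
        noise = rng.normal(0.0, config.noise_sd, size=(n, w.size))
        X = slopes[:, None] * template[None, :] + offsets[:, None] + noise
        rows.append(np.clip(X, 0.0, None))
        labels.extend([label] * n)
        ids.extend(f"c{label}_{i:03d}" for i in range(n))
    return SpectraTable(
        wavelengths_nm=w,
        X=np.vstack(rows),
        y=np.array(labels),
        sample_ids=ids,
    )


def _counts_from_fractions(
    n_class: int, fractions: tuple[float, ...]
) -> list[int]:
    """Largest-remainder apportionment of one class across splits."""
    raw = [f * n_class for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n_class - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def make_benchmark(
    config: GeneratorConfig | None = None,
    split: tuple[float, float, float] | None = None,
) -> tuple[SpectraTable, SpectraTable, SpectraTable]:
    """Generate and split into stratified train/test/online tables.

    With ``split=None`` the per-class counts reproduce the reference
    population design: 182 training, 79 test, and 90 online-validation
    samples. With fractions, per-class counts follow largest-remainder
    apportionment (within one sample of exact proportionality).
    """
    config = config or GeneratorConfig()
    table = generate(config)
    if split is not None:
        if abs(sum(split) - 1.0) > 1e-9:
            raise ValidationError("split fractions must sum to 1")
        counts = {label: _counts_from_fractions(n, split)
                  for label, n in enumerate(config.n_per_class)}
    else:
        if tuple(config.n_per_class) != DEFAULT_N_PER_CLASS:
            raise ValidationError(
                "default split counts require the default n_per_class; "
                "pass explicit split fractions otherwise"
            )
        counts = {
            label: [DEFAULT_SPLIT_COUNTS[k][label] for k in ("train", "test", "online")]
            for label in range(3)
        }
    rng = np.random.default_rng(config.seed + 1)
    parts: list[list[int]] = [[], [], []]
    assert table.y is not None
    for label in range(3):
        idx = np.where(table.y == label)[0]
        need = sum(counts[label])
        if need > idx.size:
            raise ValidationError(
                f"class {label} has {idx.size} samples but the split "
                f"requires {need}"
            )
        idx = rng.permutation(idx)
        lo = 0
        for part, c in zip(parts, counts[label]):
            part.extend(idx[lo : lo + c].tolist())
            lo += c
    train, test, online = (table.subset_rows(sorted(p)) for p in parts)
    return train, test, online
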