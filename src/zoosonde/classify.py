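"""Bi-frequency discrimination cascade.

Cells are labelled by a fixed-order rule set on the dB sum and dB
difference of the 38/120 kHz channels:

1. high sum_mvbs -> FISH (gate fitted from the bimodal sum_mvbs
   histogram with a two-component Gaussian mixture, default -119 dB);
2. delta_mvbs below the fluid window -> OTHER;
3. 2-7 dB -> KRILL, 7-25 dB -> COPEPOD, above -> OTHER;
4. a majority-vote rescue pass relabels isolated FISH cells whose
   delta_mvbs sits in a fluid window back to the surrounding fluid
   class ("lingering fluid-like echoes inside fish schools");
5. non-fish cells louder than -65 dB at 120 kHz are demoted to OTHER.

sum_mvbs here is the literal dB sum mvbs120 + mvbs38 — a discriminant
score, not a physical power sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .echogram import BiFreqCellGrid

__all__ = [
    "Label",
    "ClassifierConfig",
    "ClassMask",
    "fit_fish_threshold",
    "classify_cells",
    "rescue_fluid_in_fish",
]


class Label:
    """Integer cell labels (kept as plain ints for cheap array ops)."""

    EXCLUDED = 0
    FISH = 1
    KRILL = 2
    COPEPOD = 3
    OTHER = 4

    NAMES = {0: "EXCLUDED", 1: "FISH", 2: "KRILL", 3: "COPEPOD", 4: "OTHER"}


PROVENANCE_PRIMARY = 0
PROVENANCE_RESCUED = 1
PROVENANCE_CLAMPED = 2


@dataclass(frozen=True)
class ClassifierConfig:
    fish_sum_threshold_db: float = -119.0
    delta_other_max_db: float = 2.0
    delta_krill_max_db: float = 7.0
    delta_copepod_max_db: float = 25.0
    upper_mvbs_threshold_db: float = -65.0
    rescue_window: int = 3

    def __post_init__(self) -> None:
        if not (self.delta_other_max_db < self.delta_krill_max_db < self.delta_copepod_max_db):
            raise ValueError("delta windows must be ordered other < krill < copepod")
        for v in (
            self.fish_sum_threshold_db,
            self.delta_other_max_db,
            self.delta_krill_max_db,
            self.delta_copepod_max_db,
            self.upper_mvbs_threshold_db,
        ):
            if not np.isfinite(v):
                raise ValueError("thresholds must be finite")
        if self.rescue_window % 2 != 1 or self.rescue_window < 3:
            raise ValueError("rescue_window must be an odd integer >= 3")


@dataclass
class ClassMask:
    labels: np.ndarray       # int array, Label.*
    provenance: np.ndarray   # int array, PROVENANCE_*

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.provenance = np.asarray(self.provenance, dtype=int)
        if self.labels.shape != self.provenance.shape:
            raise ValueError("labels/provenance shape mismatch")

    def counts(self) -> dict[str, int]:
        return {
            name: int((self.labels == code).sum()) for code, name in Label.NAMES.items()
        }


def fit_fish_threshold(
    sum_mvbs_values,
    default_db: float = -119.0,
    seed: int = 0,
    n_init: int = 10,
) -> float:
    """Fish/no-fish boundary from a 2-component Gaussian mixture.

    Fits the bimodal sum_mvbs histogram by EM and returns the dB value
    between the two component means where the weighted component
    densities are equal.  Falls back to ``default_db`` with a warning
    when the fitted components are not separated by more than 1 dB.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(sum_mvbs_values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 200:
        raise ValueError("need at least 200 finite sum_mvbs values")
    span = x.max() - x.min()
    if span < 10.0:
        raise ValueError(f"sum_mvbs span {span:.1f} dB too narrow to be bimodal")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate constant input")

    gm = GaussianMixture(n_components=2, n_init=n_init, random_state=seed)
    gm.fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    (m1, m2), (s1, s2), (w1, w2) = means[order], sds[order], weights[order]

    if m2 - m1 < 1.0:
        warnings.warn(
            "mixture components overlap within 1 dB; falling back to default threshold",
            RuntimeWarning,
        )
        return default_db

    # equal weighted densities: quadratic in x
    a = 1.0 / (2 * s1**2) - 1.0 / (2 * s2**2)
    b = m2 / s2**2 - m1 / s1**2
    c = m1**2 / (2 * s1**2) - m2**2 / (2 * s2**2) + np.log((w1 * s2) / (w2 * s1))
    if abs(a) < 1e-12:
        roots = np.array([-c / b]) if b != 0 else np.array([])
    else:
        disc = b * b - 4 * a * c
        roots = np.roots([a, b, c]) if disc >= 0 else np.array([])
    roots = np.real(roots[np.isreal(roots)]) if roots.size else roots
    inside = [r for r in np.atleast_1d(roots) if m1 < r < m2]
    if not inside:
        warnings.warn(
            "no equal-density point between component means; falling back to default",
            RuntimeWarning,
        )
        return default_db
    return float(inside[0])


def classify_cells(grid: BiFreqCellGrid, cfg: ClassifierConfig | None = None) -> ClassMask:
    """Apply the cascade (fish gate, delta windows, upper threshold)."""
    cfg = cfg or ClassifierConfig()
    s = grid.sum_mvbs
    d = grid.delta_mvbs
    labels = np.full(grid.shape, Label.EXCLUDED, dtype=int)
    ok = ~grid.excluded

    fish = ok & (s > cfg.fish_sum_threshold_db)
    labels[fish] = Label.FISH
    rest = ok & ~fish
    labels[rest & (d < cfg.delta_other_max_db)] = Label.OTHER
    labels[rest & (d >= cfg.delta_other_max_db) & (d < cfg.delta_krill_max_db)] = Label.KRILL
    labels[rest & (d >= cfg.delta_krill_max_db) & (d <= cfg.delta_copepod_max_db)] = Label.COPEPOD
    labels[rest & (d > cfg.delta_copepod_max_db)] = Label.OTHER

    provenance = np.full(grid.shape, PROVENANCE_PRIMARY, dtype=int)
    mask = ClassMask(labels, provenance)
    mask = rescue_fluid_in_fish(mask, grid, cfg)

    # upper threshold: loud non-fish cells cannot be fluid-like
    loud = ok & (grid.mvbs120 > cfg.upper_mvbs_threshold_db) & (mask.labels != Label.FISH)
    mask.labels[loud] = Label.OTHER
    mask.provenance[loud] = PROVENANCE_CLAMPED
    return mask


def rescue_fluid_in_fish(
    mask: ClassMask, grid: BiFreqCellGrid, cfg: ClassifierConfig | None = None
) -> ClassMask:
    """Majority-vote rescue of fluid-like cells swallowed by the fish gate.

    Single deterministic ping-major pass: a FISH cell whose delta_mvbs
    lies in the krill or copepod window and whose neighborhood holds a
    strict majority of matching fluid labels is relabelled (provenance
    "rescued").  Decisions read the pre-pass labels only.
    """
    cfg = cfg or ClassifierConfig()
    labels = mask.labels.copy()
    prov = mask.provenance.copy()
    before = mask.labels
    d = grid.delta_mvbs
    half = cfg.rescue_window // 2
    n_i, n_j = labels.shape
    fish_cells = np.argwhere(before == Label.FISH)
    for i, j in fish_cells:
        dv = d[i, j]
        if not np.isfinite(dv):
            continue
        if cfg.delta_other_max_db <= dv < cfg.delta_krill_max_db:
            target = Label.KRILL
        elif cfg.delta_krill_max_db <= dv <= cfg.delta_copepod_max_db:
            target = Label.COPEPOD
        else:
            continue
        window = before[
            max(0, i - half) : min(n_i, i + half + 1),
            max(0, j - half) : min(n_j, j + half + 1),
        ]
        n_neighbors = window.size - 1
        if n_neighbors > 0 and (window == target).sum() > n_neighbors / 2:
            labels[i, j] = target
            prov[i, j] = PROVENANCE_RESCUED
    return ClassMask(labels, prov)
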