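"""Synthetic multi-omics data with embedded co-modules.

The generator produces a predictor matrix X (m x n_x) and a response
matrix Y (m x n_y) over the same samples, with five co-modules planted
on disjoint sample/feature coordinates against a Gaussian noise
background.  The co-modules realize two archetypes:

* **high-signal** members — cells with large absolute values across the
  module's samples (what an NMF-family method is built to find);
* **correlated low-signal** members — cells whose values are strongly
  (possibly negatively) correlated with the module pattern but small in
  magnitude (what a PLS-family method can still pick up through
  covariance with the response).

Concretely (coordinates below for the default sizes m=200, n_x=500,
n_y=300; other sizes scale the layout proportionally):

1. Module 1 (correlation structure in Y): Y columns 1-100 share one
   pattern — the first 50 with high amplitude, the last 50 with low
   amplitude; Y columns 201-230 have high amplitude of similar
   magnitude to the first 50 but follow an independent sign-mixed
   pattern, hence correlate only weakly with columns 1-100.  X columns
   1-60 carry the module pattern (1-30 high, 31-60 low amplitude).
2. Module 2 (correlation structure across samples): samples 111-200
   with X columns 201-400 and Y columns 101-200.  The first 40 of
   these samples (111-150) have very low signal, closely negatively
   correlated with the remaining 50 (151-200).  X columns 301-400 and
   Y columns 151-200 are correlated low-amplitude feature sets.
3. Module 3: a high-signal block in X (columns 401-450, samples
   31-60) with only a faint correlated tail in Y (columns 257-270 at
   low amplitude).
4. Module 4 (correlation structure across samples, spanning X and Y):
   samples 61-85 with X columns 451-500 and Y columns 231-256, all
   high amplitude; the first 10 samples (61-70) have very low,
   negatively correlated signal, like module 2's sample split.
5. Module 5: simultaneously high-signal and highly correlated (X
   columns 121-180, Y columns 271-300, samples 86-110); its member
   sets are identical under both gold standards.

Two gold standards accompany each data set: G(1) lists, per co-module,
only the high-absolute-signal members; G(2) lists every member that is
strongly correlated with the module pattern (and omits module 1's
weakly correlated high-signal columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import IndexRange, IntegratedDataset
from .evaluation import GoldStandard

__all__ = ["SimulationConfig", "SimulationBundle", "generate", "replicate_grid"]

_DEFAULT_M, _DEFAULT_NX, _DEFAULT_NY = 200, 500, 300


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the co-module simulation.

    ``signal_high`` and ``signal_low`` are the cell amplitudes of
    high-signal and correlated-low-signal members; the background is
    i.i.d. ``N(0, noise_sd^2)``.
    """

    m: int = _DEFAULT_M
    n_x: int = _DEFAULT_NX
    n_y: int = _DEFAULT_NY
    noise_sd: float = 0.25
    signal_high: float = 3.0
    signal_low: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.m, self.n_x, self.n_y) < 20:
            raise ValueError("matrices too small to hold five co-modules")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.signal_low < self.signal_high):
            raise ValueError("need 0 < signal_low < signal_high")


@dataclass(frozen=True)
class _Piece:
    """One feature range of a module within a target matrix."""

    matrix: str           # "X" or "Y"
    rng: IndexRange
    amplitude: str        # "high" or "low"
    correlated: bool = True   # shares the module pattern (True) or its own (False)


@dataclass(frozen=True)
class _ModuleSpec:
    module_id: int
    samples: IndexRange
    low_samples: IndexRange | None   # sub-range with low, negatively correlated signal
    pieces: tuple[_Piece, ...]


def _scaled(frac_start: int, frac_stop: int, size: int, default_size: int) -> IndexRange:
    start = int(round(frac_start * size / default_size))
    stop = int(round(frac_stop * size / default_size))
    return IndexRange(start, max(stop, start + 1))


def _layout(cfg: SimulationConfig) -> list[_ModuleSpec]:
    def srange(a: int, b: int) -> IndexRange:
        return _scaled(a, b, cfg.m, _DEFAULT_M)

    def xrange_(a: int, b: int) -> IndexRange:
        return _scaled(a, b, cfg.n_x, _DEFAULT_NX)

    def yrange(a: int, b: int) -> IndexRange:
        return _scaled(a, b, cfg.n_y, _DEFAULT_NY)

    specs = [
        _ModuleSpec(
            1,
            samples=srange(0, 30),
            low_samples=None,
            pieces=(
                _Piece("X", xrange_(0, 30), "high"),
                _Piece("X", xrange_(30, 60), "low"),
                _Piece("Y", yrange(0, 50), "high"),
                _Piece("Y", yrange(50, 100), "low"),
                _Piece("Y", yrange(200, 230), "high", correlated=False),
            ),
        ),
        _ModuleSpec(
            2,
            samples=srange(110, 200),
            low_samples=srange(110, 150),
            pieces=(
                _Piece("X", xrange_(200, 300), "high"),
                _Piece("X", xrange_(300, 400), "low"),
                _Piece("Y", yrange(100, 150), "high"),
                _Piece("Y", yrange(150, 200), "low"),
            ),
        ),
        _ModuleSpec(
            3,
            samples=srange(30, 60),
            low_samples=None,
            pieces=(
                _Piece("X", xrange_(400, 450), "high"),
                _Piece("Y", yrange(256, 270), "low"),
            ),
        ),
        _ModuleSpec(
            4,
            samples=srange(60, 85),
            low_samples=srange(60, 70),
            pieces=(
                _Piece("X", xrange_(450, 500), "high"),
                _Piece("Y", yrange(230, 256), "high"),
            ),
        ),
        _ModuleSpec(
            5,
            samples=srange(85, 110),
            low_samples=None,
            pieces=(
                _Piece("X", xrange_(120, 180), "high"),
                _Piece("Y", yrange(270, 300), "high"),
            ),
        ),
    ]
    _validate_layout(specs, cfg)
    return specs


def _validate_layout(specs: list[_ModuleSpec], cfg: SimulationConfig) -> None:
    used = {"X": np.zeros(cfg.n_x, dtype=bool), "Y": np.zeros(cfg.n_y, dtype=bool)}
    used_samples = np.zeros(cfg.m, dtype=bool)
    for spec in specs:
        r = spec.samples
        if r.stop > cfg.m or used_samples[r.start:r.stop].any():
            raise ValueError(f"module {spec.module_id} sample range overlaps or exceeds m")
        used_samples[r.start:r.stop] = True
        for piece in spec.pieces:
            mask = used[piece.matrix]
            if piece.rng.stop > len(mask) or mask[piece.rng.start:piece.rng.stop].any():
                raise ValueError(
                    f"module {spec.module_id} feature range overlaps in {piece.matrix}"
                )
            mask[piece.rng.start:piece.rng.stop] = True


@dataclass
class SimulationBundle:
    """One generated data set with its two gold standards."""

    X: np.ndarray
    Y: np.ndarray
    G1: GoldStandard
    G2: GoldStandard
    config: SimulationConfig
    sample_labels: list[str]
    x_labels: list[str]
    y_labels: list[str]
    module_specs: list[_ModuleSpec] = field(default_factory=list)

    def to_dataset(self) -> IntegratedDataset:
        return IntegratedDataset(
            data=np.hstack([self.X, self.Y]),
            x_blocks=[IndexRange(0, self.X.shape[1])],
            y_block=IndexRange(self.X.shape[1], self.X.shape[1] + self.Y.shape[1]),
            sample_labels=self.sample_labels,
            feature_labels=self.x_labels + self.y_labels,
            feature_types=["X", "Y"],
        )


def generate(config: SimulationConfig) -> SimulationBundle:
    """Generate one simulated data set and both gold standards.

    Each module draws one sample pattern (magnitudes near 1, positive
    except for the designated low-signal sample sub-range, which is
    negative with magnitude ``signal_low / signal_high``) and one
    amplitude per member feature (base amplitude jittered by +-20% with
    a random sign, so member features are positively or negatively
    correlated).  Member cells are the outer product of the two;
    weakly-correlated pieces draw an independent sign-mixed sample
    pattern.  The same seed reproduces the bundle bit for bit.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    specs = _layout(cfg)
    X = rng.normal(0.0, cfg.noise_sd, size=(cfg.m, cfg.n_x))
    Y = rng.normal(0.0, cfg.noise_sd, size=(cfg.m, cfg.n_y))
    matrices = {"X": X, "Y": Y}

    sample_labels = [f"S{i + 1:04d}" for i in range(cfg.m)]
    x_labels = [f"x{j + 1:04d}" for j in range(cfg.n_x)]
    y_labels = [f"y{j + 1:04d}" for j in range(cfg.n_y)]
    labels = {"X": x_labels, "Y": y_labels}

    g1_modules: list[frozenset[str]] = []
    g2_modules: list[frozenset[str]] = []
    for spec in specs:
        n_s = spec.samples.width
        pattern = rng.uniform(0.9, 1.1, size=n_s)
        high_samples = np.ones(n_s, dtype=bool)
        if spec.low_samples is not None:
            low = np.zeros(n_s, dtype=bool)
            low[spec.low_samples.start - spec.samples.start:
                spec.low_samples.stop - spec.samples.start] = True
            pattern[low] *= -(cfg.signal_low / cfg.signal_high)
            high_samples = ~low

        g1: set[str] = set()
        g2: set[str] = set()
        sample_ids = [f"sample:{sample_labels[i]}" for i in spec.samples.indices]
        g1.update(np.asarray(sample_ids, dtype=object)[high_samples])
        g2.update(sample_ids)

        for piece in spec.pieces:
            width = piece.rng.width
            base = cfg.signal_high if piece.amplitude == "high" else cfg.signal_low
            amps = base * rng.uniform(0.8, 1.2, size=width) * rng.choice([-1.0, 1.0], size=width)
            if piece.correlated:
                s = pattern
            else:
                # independent, sign-mixed pattern: high signal, weak
                # correlation with the module's main pattern
                s = rng.uniform(0.9, 1.1, size=n_s) * rng.choice([-1.0, 1.0], size=n_s)
            M = matrices[piece.matrix]
            M[spec.samples.start:spec.samples.stop, piece.rng.start:piece.rng.stop] += np.outer(
                s, amps
            )
            ids = [f"{piece.matrix}:{labels[piece.matrix][j]}" for j in piece.rng.indices]
            if piece.amplitude == "high":
                g1.update(ids)
            if piece.correlated:
                g2.update(ids)
        g1_modules.append(frozenset(g1))
        g2_modules.append(frozenset(g2))

    return SimulationBundle(
        X=X,
        Y=Y,
        G1=GoldStandard("NMF", g1_modules),
        G2=GoldStandard("PLS", g2_modules),
        config=cfg,
        sample_labels=sample_labels,
        x_labels=x_labels,
        y_labels=y_labels,
        module_specs=specs,
    )


def replicate_grid(
    config: SimulationConfig,
    noise_levels: list[float],
    n_replicates: int,
) -> list[SimulationBundle]:
    """Generate ``n_replicates`` bundles per noise level.

    Bundles share the base configuration; each gets ``noise_sd`` from
    the grid and a deterministic per-replicate seed (master seed +
    running index), so the whole grid is reproducible from one seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    bundles = []
    idx = 0
    for noise in noise_levels:
        for _ in range(n_replicates):
            bundles.append(generate(replace(config, noise_sd=float(noise), seed=config.seed + idx)))
            idx += 1
    return bundles
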