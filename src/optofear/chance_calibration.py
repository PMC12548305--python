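"""Chance-level calibration of the jitter test by ISI-order shuffling.

Permuting the order of a unit's inter-spike intervals preserves its firing
rate, ISI distribution, and burst structure, but destroys any alignment of
spikes to the stimulation timeline. Re-running the full jitter test on such
shuffled data therefore estimates the fraction of units the detector would
call responsive by chance, which is the yardstick the observed fraction is
compared against (paired per recording site, Wilcoxon signed-rank).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .responsiveness import detect_population
from .types import InvalidParameterError, JitterConfig, SpikeTrain, StimProtocol

log = logging.getLogger("optofear")


@dataclass(frozen=True)
class ShuffleResult:
    """Observed responsive fraction vs its ISI-shuffle chance distribution."""

    site_id: str
    observed_fraction: float
    chance_fractions: np.ndarray
    n_shuffles: int

    def __post_init__(self) -> None:
        cf = np.asarray(self.chance_fractions, dtype=float)
        object.__setattr__(self, "chance_fractions", cf)
        if cf.size != self.n_shuffles:
            raise InvalidParameterError("chance_fractions length must equal n_shuffles")
        if not (0.0 <= self.observed_fraction <= 1.0) or np.any((cf < 0) | (cf > 1)):
            raise InvalidParameterError("fractions must lie in [0, 1]")

    def chance_band(self, coverage: float = 0.95):
        """Empirical central band of the chance fractions."""
        alpha = (1.0 - coverage) / 2.0
        return tuple(np.quantile(self.chance_fractions, [alpha, 1.0 - alpha]))

    @property
    def excess_fraction(self) -> float:
        """Chance-corrected estimate of the truly stimulus-locked fraction.

        The pointwise jitter test runs 12 uncorrected bins per unit, so its
        per-unit chance level c is far from zero. Under the mixture model
        observed = theta + (1 - theta) * c (a truly locked unit is detected
        via its response; an unlocked one is caught with probability c), the
        estimate is theta = (observed - c) / (1 - c) with c the mean
        ISI-shuffle chance fraction.
        """
        c = float(self.chance_fractions.mean())
        if c >= 1.0:
            return 0.0
        return float((self.observed_fraction - c) / (1.0 - c))


def shuffle_isi(train: SpikeTrain, seed=0) -> SpikeTrain:
    """Randomly permute the order of a train's inter-spike intervals.

    The first spike time, the spike count, and the ISI multiset are
    preserved; the last spike time is pinned to its original value (the
    permuted prefix sums reproduce it only up to float accumulation error,
    ~1e-13 s, well below any sampling resolution). Trains with fewer than
    two spikes are returned unchanged.
    """
    if train.n_spikes < 2:
        return train
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    isis = train.isis()
    shuffled = rng.permutation(isis)
    times = train.spike_times[0] + np.concatenate(([0.0], np.cumsum(shuffled)))
    times[-1] = train.spike_times[-1]
    times = np.maximum.accumulate(times)  # guard rounding-induced inversions
    return SpikeTrain(train.unit_id, times, train.duration)


def chance_fraction(
    trains,
    protocol: StimProtocol,
    config: JitterConfig | None = None,
    n_shuffles: int = 100,
    seed: int = 0,
    site_id: str = "site0",
    observed_calls=None,
) -> ShuffleResult:
    """Estimate the detector's chance-level responsive fraction.

    Each replicate ISI-shuffles every train (independent streams derived
    from ``seed``) and re-runs the full jitter test with the same config;
    the observed fraction is computed on the unshuffled trains (or taken
    from ``observed_calls`` when the caller already detected them).
    """
    trains = list(trains)
    if not trains:
        raise InvalidParameterError("no spike trains supplied")
    if n_shuffles < 1:
        raise InvalidParameterError("n_shuffles must be >= 1")
    config = config or JitterConfig()

    ss = np.random.SeedSequence(seed)
    detect_seed_obs, *replicate_seeds = ss.spawn(n_shuffles + 1)

    if observed_calls is None:
        observed_calls = detect_population(
            trains, protocol, config,
            seed=int(np.random.default_rng(detect_seed_obs).integers(2**31)),
        )
    elif len(observed_calls) != len(trains):
        raise InvalidParameterError("observed_calls must align with trains")
    observed = float(np.mean([c.responsive for c in observed_calls]))

    fractions = np.empty(n_shuffles)
    for r, rep_seed in enumerate(replicate_seeds):
        rep_rng = np.random.default_rng(rep_seed)
        shuffled = [shuffle_isi(t, rep_rng) for t in trains]
        rep_calls = detect_population(
            shuffled, protocol, config, seed=int(rep_rng.integers(2**31))
        )
        fractions[r] = np.mean([c.responsive for c in rep_calls])
    return ShuffleResult(
        site_id=site_id,
        observed_fraction=observed,
        chance_fractions=fractions,
        n_shuffles=n_shuffles,
    )


def signrank_compare(per_site_observed, per_site_chance, variant: str = "wilcoxon"):
    """Paired comparison of observed vs chance responsive fractions.

    Wilcoxon signed-rank on the paired differences, zero differences
    dropped; the reported statistic is the sum of positive ranks (W+), with
    an exact two-sided p for fewer than 26 non-zero pairs and the normal
    approximation otherwise. ``variant="sign"`` runs a plain sign
    (binomial) test instead.
    """
    obs = np.asarray(per_site_observed, dtype=float)
    cha = np.asarray(per_site_chance, dtype=float)
    if obs.shape != cha.shape or obs.ndim != 1 or obs.size == 0:
        raise InvalidParameterError("paired vectors of equal length required")
    if obs.size < 5:
        log.warning("fewer than 5 pairs: the paired test has little power")
    d = obs - cha
    d = d[d != 0.0]
    if d.size == 0:
        log.warning("all paired differences are zero; p = 1")
        return 0.0, 1.0
    if variant == "sign":
        n_pos = int(np.sum(d > 0))
        res = stats.binomtest(n_pos, d.size, 0.5, alternative="two-sided")
        return float(n_pos), float(res.pvalue)
    if variant != "wilcoxon":
        raise InvalidParameterError("variant must be 'wilcoxon' or 'sign'")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    method = "exact" if d.size < 26 else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on ties with exact method
        res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return w_plus, float(res.pvalue)
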