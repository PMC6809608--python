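"""Synthetic behaviour and EEG with the structure the analyses assume.

The generator emulates the study conditions of a two-by-two design
(deliberate/arbitrary x easy/hard, 90 trials per condition, 18 subjects):

* ratings of 50 charity-like items on a 1-7 scale, paired so that *hard*
  pairs differ by exactly 1 rating point and *easy* pairs by at least 4;
* gamma-distributed RTs with condition means 2.13 / 2.52 / 0.98 / 1.00 s;
* congruent-choice (consistency) probabilities 0.99 / 0.83 / 0.54 / 0.49;
* continuous 512 Hz EEG with 1/f-shaped noise, a negative pre-movement
  ramp (-2.5 µV peak at Cz, onset 1.2 s before response) injected in
  arbitrary trials only, a lateralized C3/C4 motor template by response
  hand, radial-EOG saccade bursts, occasional blink transients and
  above-threshold artifact spikes.

Every stochastic step derives its stream from the seed passed in, so the
same seed reproduces byte-identical tables and recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from driftrace.erp_pipeline import EOG_LABELS, Recording

logger = logging.getLogger("driftrace")

CONDITION_ORDER = (
    ("deliberate", "easy"),
    ("deliberate", "hard"),
    ("arbitrary", "easy"),
    ("arbitrary", "hard"),
)

#: Observed condition-mean RTs the generator is tuned to, seconds.
RT_MEANS_S = {
    ("deliberate", "easy"): 2.13,
    ("deliberate", "hard"): 2.52,
    ("arbitrary", "easy"): 0.98,
    ("arbitrary", "hard"): 1.00,
}

#: Observed congruent-choice probabilities per condition.
CONSISTENCY_P = {
    ("deliberate", "easy"): 0.99,
    ("deliberate", "hard"): 0.83,
    ("arbitrary", "easy"): 0.54,
    ("arbitrary", "hard"): 0.49,
}


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic dataset.

    EEG amplitudes are in µV, times in seconds, rates in Hz.  The RP
    template is a linear ramp from 0 at ``-rp_onset_s`` to ``rp_peak_uv``
    at the response (a quadratic variant is available), injected at Cz
    with ``spatial_falloff`` on the neighbouring scalp channels, and only
    in arbitrary trials.  The lateralized template puts ``lrp_peak_uv`` on
    the electrode contralateral to the response hand over the final
    ``lrp_window_s``.
    """

    n_subjects: int = 18
    trials_per_condition: int = 90
    rt_means: dict = field(default_factory=lambda: dict(RT_MEANS_S))
    rt_shape: float = 6.0
    consistency: dict = field(default_factory=lambda: dict(CONSISTENCY_P))

    rate: float = 512.0
    scalp_labels: tuple[str, ...] = ("Cz", "C3", "C4", "Fz", "Pz")
    noise_exponent: float = 1.0
    noise_amplitude_uv: float = 10.0

    rp_peak_uv: float = -2.5
    rp_onset_s: float = 1.2
    rp_shape: str = "linear"  # or "quadratic"
    rp_release_s: float = 0.2  # post-response decay back to 0
    spatial_falloff: float = 0.4

    lrp_peak_uv: float = -1.0
    lrp_window_s: float = 0.3

    saccade_rate_hz: float = 3.3
    saccade_amp_uv: float = 30.0
    saccade_duration_s: float = 0.01
    blink_rate_hz: float = 0.05
    blink_amp_uv: float = 60.0
    artifact_rate_hz: float = 0.005
    artifact_amp_uv: float = 120.0

    fixation_range_s: tuple[float, float] = (1.0, 1.5)
    feedback_s: float = 1.0  # post-response highlight before the next trial
    lead_in_s: float = 3.0
    lead_out_s: float = 3.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if any(not 0 <= p <= 1 for p in self.consistency.values()):
            raise ValueError("consistency values must be probabilities")
        if any(m <= 0 for m in self.rt_means.values()):
            raise ValueError("RT means must be positive")
        if self.rp_shape not in ("linear", "quadratic"):
            raise ValueError("rp_shape must be 'linear' or 'quadratic'")

    @property
    def labels(self) -> list[str]:
        return list(self.scalp_labels) + list(EOG_LABELS)


# -- ratings and pairs --------------------------------------------------------


def _build_pairs(
    ratings: pd.DataFrame, difficulty: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Sample ``n`` item pairs with the required rating difference.

    Hard pairs differ by exactly one rating point, easy pairs by at least
    four.  Raises when the rating spread admits no such pair.
    """
    r = ratings["rating"].to_numpy()
    idx = np.arange(len(r))
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    upper = ii < jj
    diff = np.abs(r[ii] - r[jj])
    ok = upper & ((diff == 1) if difficulty == "hard" else (diff >= 4))
    cand = np.argwhere(ok)
    if len(cand) == 0:
        raise ValueError(f"rating spread admits no {difficulty} pairs")
    pick = cand[rng.integers(0, len(cand), size=n)]
    hi = np.where(r[pick[:, 0]] >= r[pick[:, 1]], pick[:, 0], pick[:, 1])
    lo = np.where(r[pick[:, 0]] >= r[pick[:, 1]], pick[:, 1], pick[:, 0])
    return pd.DataFrame(
        {
            "difficulty": difficulty,
            "item_hi": hi,
            "item_lo": lo,
            "rating_hi": r[hi],
            "rating_lo": r[lo],
        }
    )


def generate_ratings_and_pairs(
    seed: int | np.random.Generator,
    n_items: int = 50,
    n_pairs_per_difficulty: int = 45,
    max_retries: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Item ratings (1-7) plus a trial pair list per difficulty.

    When a drawn rating distribution is too narrow to form the required
    pairs it is regenerated with a widened (uniform over the full scale)
    spread; equal counts of easy and hard pairs are returned.
    """
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        if attempt == 0:
            ratings = rng.binomial(6, 0.5, size=n_items) + 1  # centred spread
        else:
            ratings = rng.integers(1, 8, size=n_items)  # widened: uniform 1-7
        table = pd.DataFrame({"item": np.arange(n_items), "rating": ratings})
        try:
            hard = _build_pairs(table, "hard", n_pairs_per_difficulty, rng)
            easy = _build_pairs(table, "easy", n_pairs_per_difficulty, rng)
        except ValueError:
            logger.warning("rating spread too narrow (attempt %d); widening", attempt)
            continue
        pairs = pd.concat([easy, hard], ignore_index=True)
        return table, pairs
    raise ValueError("could not form the required pairs after widening the spread")


# -- behaviour ----------------------------------------------------------------


def generate_behavior(
    cfg: GeneratorConfig, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Trial table for all subjects.

    Per condition: RT ~ gamma(shape, mean/shape); the choice falls on the
    higher-rated alternative with the condition's congruent probability;
    the higher-rated item's side (hence the response hand) is balanced at
    random.  Columns include the ratings needed for the consistency grade.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for subject in range(cfg.n_subjects):
        srng = rng.spawn(1)[0]
        _, pairs = generate_ratings_and_pairs(
            srng, n_pairs_per_difficulty=max(45, cfg.trials_per_condition)
        )
        for dec, diff in CONDITION_ORDER:
            n = cfg.trials_per_condition
            pool = pairs[pairs["difficulty"] == diff]
            sel = pool.iloc[srng.integers(0, len(pool), size=n)].reset_index(drop=True)
            mean = cfg.rt_means[(dec, diff)]
            rt = srng.gamma(cfg.rt_shape, mean / cfg.rt_shape, size=n)
            congruent = srng.random(n) < cfg.consistency[(dec, diff)]
            hi_side = np.where(srng.random(n) < 0.5, "left", "right")
            other = np.where(hi_side == "left", "right", "left")
            hand = np.where(congruent, hi_side, other)
            frames.append(
                pd.DataFrame(
                    {
                        "subject": subject,
                        "trial": np.arange(n),
                        "block": np.arange(n) // 9,
                        "decision_type": dec,
                        "difficulty": diff,
                        "rt": rt,
                        "congruent_choice": congruent,
                        "hand": hand,
                        "rating_hi": sel["rating_hi"].to_numpy(),
                        "rating_lo": sel["rating_lo"].to_numpy(),
                        "rating_chosen": np.where(
                            congruent, sel["rating_hi"], sel["rating_lo"]
                        ),
                        "rating_unchosen": np.where(
                            congruent, sel["rating_lo"], sel["rating_hi"]
                        ),
                        "wrong_key": False,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# -- EEG ----------------------------------------------------------------------


def one_over_f_noise(
    n_samples: int, rate: float, exponent: float, rms_uv: float, rng: np.random.Generator
) -> np.ndarray:
    """Autocorrelated noise with a 1/f^exponent power spectrum.

    White Gaussian noise is shaped in the frequency domain by
    f^(-exponent/2) (DC removed) and rescaled to the requested RMS.
    """
    if rms_uv == 0:
        return np.zeros(n_samples)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n_samples)
    x *= rms_uv / x.std()
    return x


def _rp_template(n_ramp: int, n_release: int, peak: float, shape: str) -> np.ndarray:
    """Pre-movement ramp ending at ``peak`` plus a short release to 0."""
    u = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
    ramp = peak * (u if shape == "linear" else u**2)
    release = peak * np.linspace(1.0, 0.0, n_release, endpoint=False)
    return np.concatenate([ramp, release])


def generate_eeg(
    trials: pd.DataFrame,
    cfg: GeneratorConfig,
    seed: int | np.random.Generator,
) -> tuple[Recording, pd.DataFrame]:
    """Continuous recording for one subject's trial table.

    Trials are laid out sequentially: fixation drawn uniformly from
    ``fixation_range_s``, then the stimulus, the response after the
    trial's RT, and ``feedback_s`` of post-response screen.  Returns the
    :class:`Recording` (with stimulus and response events) and a copy of
    the trial table carrying ``stimulus_sample``/``response_sample``.

    Injected structure: the RP ramp at Cz (scaled by ``spatial_falloff``
    on the other scalp channels) in arbitrary trials only; the lateralized
    template on the channel contralateral to the response hand; saccade
    bursts and blink transients on the EOG channels; rare high-amplitude
    artifact spikes on random scalp channels.
    """
    if trials["subject"].nunique() != 1:
        raise ValueError("generate_eeg expects a single subject's trials")
    rng = np.random.default_rng(seed)
    rate = cfg.rate
    n_trials = len(trials)

    fix = rng.uniform(*cfg.fixation_range_s, size=n_trials)
    min_gap = cfg.feedback_s + cfg.fixation_range_s[0]
    stim_t = np.empty(n_trials)
    resp_t = np.empty(n_trials)
    t = cfg.lead_in_s
    rts = trials["rt"].to_numpy()
    for i in range(n_trials):
        t += fix[i]
        stim_t[i] = t
        resp_t[i] = t + rts[i]
        t = resp_t[i] + cfg.feedback_s
    n_samples = int(round((t + cfg.lead_out_s) * rate))
    if min_gap < 2.0:
        logger.warning("inter-trial spacing %.2f s is short for baselining", min_gap)

    labels = cfg.labels
    data = np.empty((len(labels), n_samples))
    for ch in range(len(labels)):
        data[ch] = one_over_f_noise(
            n_samples, rate, cfg.noise_exponent, cfg.noise_amplitude_uv, rng.spawn(1)[0]
        )

    stim_s = np.round(stim_t * rate).astype(int)
    resp_s = np.round(resp_t * rate).astype(int)

    # RP ramp, arbitrary trials only, Cz plus attenuated neighbours
    n_ramp = int(round(cfg.rp_onset_s * rate))
    n_rel = int(round(cfg.rp_release_s * rate))
    rp = _rp_template(n_ramp, n_rel, cfg.rp_peak_uv, cfg.rp_shape)
    gains = {
        lab: (1.0 if lab == "Cz" else cfg.spatial_falloff) for lab in cfg.scalp_labels
    }
    arb = (trials["decision_type"] == "arbitrary").to_numpy()
    for i in np.flatnonzero(arb):
        a = resp_s[i] - n_ramp
        b = a + len(rp)
        if a < 0 or b > n_samples:
            continue
        for lab, g in gains.items():
            data[labels.index(lab), a:b] += g * rp

    # lateralized motor template, contralateral to the response hand
    n_lrp = int(round(cfg.lrp_window_s * rate))
    lrp = _rp_template(n_lrp, n_rel, cfg.lrp_peak_uv, "linear")
    hands = trials["hand"].to_numpy()
    for i in range(n_trials):
        contra = "C4" if hands[i] == "left" else "C3"
        a = resp_s[i] - n_lrp
        b = a + len(lrp)
        if a < 0 or b > n_samples:
            continue
        data[labels.index(contra), a:b] += lrp

    # saccade bursts on all four EOG channels (shared, as a radial signal)
    n_sacc = rng.poisson(cfg.saccade_rate_hz * n_samples / rate)
    sacc_at = np.sort(rng.integers(0, n_samples, size=n_sacc))
    n_burst = max(int(round(cfg.saccade_duration_s * rate)), 3)
    tt = np.arange(n_burst) / rate
    burst = (
        np.sin(2 * np.pi * 45.0 * tt)
        * np.hanning(n_burst)
        * cfg.saccade_amp_uv
    )
    eog_idx = [labels.index(l) for l in EOG_LABELS]
    for s in sacc_at:
        b = min(s + n_burst, n_samples)
        for ch in eog_idx:
            data[ch, s:b] += burst[: b - s]

    # blink transients (slow, vertical EOG pair)
    n_blinks = rng.poisson(cfg.blink_rate_hz * n_samples / rate)
    n_bl = int(round(0.3 * rate))
    bl = cfg.blink_amp_uv * np.hanning(n_bl)
    for s in rng.integers(0, max(n_samples - n_bl, 1), size=n_blinks):
        for ch in eog_idx[2:]:
            data[ch, s : s + n_bl] += bl

    # rare above-threshold artifact spikes on random scalp channels
    n_art = rng.poisson(cfg.artifact_rate_hz * n_samples / rate)
    n_sp = int(round(0.05 * rate))
    spike = cfg.artifact_amp_uv * np.sin(np.pi * np.arange(n_sp) / n_sp)
    for s in rng.integers(0, max(n_samples - n_sp, 1), size=n_art):
        ch = rng.integers(0, len(cfg.scalp_labels))
        data[ch, s : s + n_sp] += spike * rng.choice([-1.0, 1.0])

    kinds = np.where(hands == "left", "response-left", "response-right")
    events = pd.DataFrame(
        {
            "sample": np.concatenate([stim_s, resp_s]),
            "kind": np.concatenate([np.full(n_trials, "stimulus"), kinds]),
            "trial": np.concatenate([trials["trial"], trials["trial"]]),
        }
    ).sort_values("sample", ignore_index=True)

    rec = Recording(data=data, rate=rate, labels=labels, events=events)
    out = trials.copy().reset_index(drop=True)
    out["stimulus_sample"] = stim_s
    out["response_sample"] = resp_s
    return rec, out
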