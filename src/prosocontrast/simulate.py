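"""Synthetic token-level data with the hierarchical structure the analysis
assumes: a 2-group x 2-condition design, crossed participant/item random
intercepts on the log-odds of two-AP phrasing, acoustic realisations that
respect (or deliberately straddle) the 10% classification thresholds, and
hinting scores monotonically linked to each participant's phrasing-marking
propensity.

The generative model is the analysis model read forwards: a logistic
regression with crossed normal random intercepts decides each token's
latent phrasing, and the four acoustic scalars are then realised so the
threshold classifier reconstructs that label (exactly, when
``criterion_noise`` is 0).  Default coefficients and variance components
are the crossed-intercept fit reported for the original case-control
study; default design sizes are that study's (10 participants per group,
20 items, of which half given and half contrastive).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .annotations import Dataset, ParticipantMeta, TokenAnnotation
from .errors import ConfigError


@dataclass(frozen=True)
class TrueCoefficients:
    """Fixed effects on the log-odds of TWO_AP (treatment coding,
    references: given condition, HC group)."""

    intercept: float = -1.2384
    condition_effect: float = 2.5982
    group_effect: float = 0.5948
    interaction: float = -2.0395


@dataclass(frozen=True)
class RatioRanges:
    """Uniform ranges for the S2/S1 duration ratio and H/L f0 ratio, per
    latent label.  TWO_AP ranges must sit at/above the 1.10 threshold and
    ONE_AP ranges strictly below it."""

    two_ap_dur: tuple[float, float] = (1.12, 1.40)
    one_ap_dur: tuple[float, float] = (0.90, 1.08)
    two_ap_f0: tuple[float, float] = (1.12, 1.45)
    one_ap_f0: tuple[float, float] = (0.90, 1.08)


@dataclass(frozen=True)
class HintingLink:
    """Gaussian hinting score around the group mean, shifted by
    propensity_weight x (participant match proportion - group mean
    proportion), rounded and clamped to [0, 20]."""

    hc_mean: float = 17.9
    sz_mean: float = 14.9
    sd: float = 1.8
    propensity_weight: float = 15.0


@dataclass(frozen=True)
class GeneratorConfig:
    n_participants_per_group: int = 10
    n_items: int = 20
    true_coefficients: TrueCoefficients = field(default_factory=TrueCoefficients)
    var_participant: float = 0.79490
    var_item: float = 0.35673
    base_dur_s1: float = 0.14  # s; typical full-syllable duration
    base_f0_l: float = 120.0  # Hz; typical adult early-L minimum
    dur_sigma: float = 0.15  # lognormal sigma of S1 duration
    f0_sigma: float = 0.08  # lognormal sigma of the L minimum
    ratio_ranges: RatioRanges = field(default_factory=RatioRanges)
    criterion_noise: float = 0.0
    dropout_prob: float = 0.1925  # matches the study's 80.75% retention
    hinting_link: HintingLink = field(default_factory=HintingLink)
    seed: int = 0

    def validate(self, threshold: float = 1.10) -> None:
        if self.n_participants_per_group < 1 or self.n_items < 1:
            raise ConfigError("design sizes must be >= 1")
        if self.var_participant < 0 or self.var_item < 0:
            raise ConfigError("variance components must be >= 0")
        if not (0 <= self.criterion_noise < 1 and 0 <= self.dropout_prob < 1):
            raise ConfigError("probabilities must lie in [0, 1)")
        if self.base_dur_s1 <= 0 or self.base_f0_l <= 0:
            raise ConfigError("acoustic bases must be strictly positive")
        rr = self.ratio_ranges
        for name, (lo, hi) in (
            ("two_ap_dur", rr.two_ap_dur),
            ("one_ap_dur", rr.one_ap_dur),
            ("two_ap_f0", rr.two_ap_f0),
            ("one_ap_f0", rr.one_ap_f0),
        ):
            if not 0 < lo <= hi:
                raise ConfigError(f"ratio range {name} must satisfy 0 < lo <= hi")
        for name, (lo, _) in (("two_ap_dur", rr.two_ap_dur), ("two_ap_f0", rr.two_ap_f0)):
            if lo < threshold:
                raise ConfigError(
                    f"TWO_AP ratio range {name} must start at or above {threshold}"
                )
        for name, (_, hi) in (("one_ap_dur", rr.one_ap_dur), ("one_ap_f0", rr.one_ap_f0)):
            if hi >= threshold:
                raise ConfigError(
                    f"ONE_AP ratio range {name} must end strictly below {threshold}"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "GeneratorConfig":
        payload = dict(payload)
        if "true_coefficients" in payload and isinstance(
            payload["true_coefficients"], dict
        ):
            payload["true_coefficients"] = TrueCoefficients(**payload["true_coefficients"])
        if "ratio_ranges" in payload and isinstance(payload["ratio_ranges"], dict):
            payload["ratio_ranges"] = RatioRanges(
                **{k: tuple(v) for k, v in payload["ratio_ranges"].items()}
            )
        if "hinting_link" in payload and isinstance(payload["hinting_link"], dict):
            payload["hinting_link"] = HintingLink(**payload["hinting_link"])
        return cls(**payload)


#: Group summary distributions for the metadata-only fixture: the hinting
#: theory-of-mind score, total task time (s) and number of speaking turns.
SUMMARY_DEFAULTS: dict[str, dict[str, tuple[float, float]]] = {
    "hinting": {"HC": (17.9, 1.5), "SZ": (14.9, 2.1)},
    "total_time": {"HC": (169.10, 41.01), "SZ": (208.8, 63.46)},
    "speaking_turns": {"HC": (30.0, 2.91), "SZ": (31.5, 4.6)},
}


def _participant_ids(config: GeneratorConfig) -> list[tuple[str, str]]:
    ids = []
    for group in ("HC", "SZ"):
        for i in range(1, config.n_participants_per_group + 1):
            ids.append((f"{group}{i:03d}", group))
    return ids


def generate_with_latent(config: GeneratorConfig) -> tuple[Dataset, "np.ndarray"]:
    """Generate a dataset plus the per-token latent TWO_AP indicators
    (before criterion noise), in token order."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    coef = config.true_coefficients
    rr = config.ratio_ranges

    participants = _participant_ids(config)
    u = rng.normal(0.0, np.sqrt(config.var_participant), size=len(participants))
    v = rng.normal(0.0, np.sqrt(config.var_item), size=config.n_items)
    # balanced condition assignment, fixed per item (a landmark pair is
    # either a repeated or a contrasting noun by design)
    conditions = ["given" if j % 2 == 0 else "contrastive" for j in range(config.n_items)]

    tokens: list[TokenAnnotation] = []
    latent: list[int] = []
    match_count = {pid: 0 for pid, _ in participants}
    token_count = {pid: 0 for pid, _ in participants}

    for p_idx, (pid, group) in enumerate(participants):
        for j in range(config.n_items):
            condition = conditions[j]
            is_contr = condition == "contrastive"
            is_sz = group == "SZ"
            eta = (
                coef.intercept
                + coef.condition_effect * is_contr
                + coef.group_effect * is_sz
                + coef.interaction * (is_contr and is_sz)
                + u[p_idx]
                + v[j]
            )
            p_two = 1.0 / (1.0 + np.exp(-eta))
            two_ap = bool(rng.random() < p_two)
            realized = two_ap
            if config.criterion_noise > 0 and rng.random() < config.criterion_noise:
                realized = not realized

            dur_s1 = float(
                np.exp(rng.normal(np.log(config.base_dur_s1), config.dur_sigma))
            )
            f0_l = float(np.exp(rng.normal(np.log(config.base_f0_l), config.f0_sigma)))
            dur_lo, dur_hi = rr.two_ap_dur if realized else rr.one_ap_dur
            f0_lo, f0_hi = rr.two_ap_f0 if realized else rr.one_ap_f0
            dur_s2 = dur_s1 * float(rng.uniform(dur_lo, dur_hi))
            f0_h = f0_l * float(rng.uniform(f0_lo, f0_hi))

            flagged = rng.random() < config.dropout_prob
            disfluent = False
            labeling_error = False
            if flagged:
                if rng.random() < 0.5:
                    disfluent = True
                else:
                    labeling_error = True

            tokens.append(
                TokenAnnotation(
                    token_id=f"{pid}_item{j + 1:03d}",
                    participant_id=pid,
                    group=group,
                    item_id=f"item{j + 1:03d}",
                    condition=condition,
                    dur_s1=dur_s1,
                    dur_s2=dur_s2,
                    f0_l=f0_l,
                    f0_h=f0_h,
                    disfluent=disfluent,
                    labeling_error=labeling_error,
                )
            )
            latent.append(int(two_ap))
            expected_two = is_contr
            match_count[pid] += int(realized == expected_two)
            token_count[pid] += 1

    # group-level mean match proportion, then the hinting link
    props = {pid: match_count[pid] / token_count[pid] for pid, _ in participants}
    group_mean_prop = {
        grp: float(np.mean([props[pid] for pid, g in participants if g == grp]))
        for grp in ("HC", "SZ")
    }
    link = config.hinting_link
    metas = []
    for pid, group in participants:
        base = link.hc_mean if group == "HC" else link.sz_mean
        loc = base + link.propensity_weight * (props[pid] - group_mean_prop[group])
        score = int(round(rng.normal(loc, link.sd)))
        metas.append(
            ParticipantMeta(
                participant_id=pid,
                group=group,
                hinting_score=int(np.clip(score, 0, 20)),
            )
        )

    dataset = Dataset(
        tokens=tokens,
        participants=metas,
        provenance=[
            "synthetic data: crossed random-intercept logistic generator",
            f"seed={config.seed}, n/group={config.n_participants_per_group}, "
            f"items={config.n_items}",
        ],
    )
    dataset.validate()
    return dataset, np.asarray(latent, dtype=int)


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Generate a synthetic dataset; fully reproducible from config.seed."""
    dataset, _ = generate_with_latent(config)
    return dataset


def generate_summary_fixture(
    config: GeneratorConfig,
    summary_stats: dict | None = None,
) -> list[ParticipantMeta]:
    """Participant metadata only, for exercising the t-test stage alone.

    Hinting score, total time and speaking turns are drawn from group
    normals (defaults: the case-control study's printed group summaries).
    """
    config.validate()
    stats = summary_stats or SUMMARY_DEFAULTS
    rng = np.random.default_rng(config.seed)
    metas = []
    for pid, group in _participant_ids(config):
        h_mean, h_sd = stats["hinting"][group]
        t_mean, t_sd = stats["total_time"][group]
        s_mean, s_sd = stats["speaking_turns"][group]
        hinting = int(np.clip(int(round(rng.normal(h_mean, h_sd))), 0, 20))
        total_time = float(max(rng.normal(t_mean, t_sd), 0.0))
        turns = int(max(int(round(rng.normal(s_mean, s_sd))), 0))
        metas.append(
            ParticipantMeta(
                participant_id=pid,
                group=group,
                hinting_score=hinting,
                total_time=total_time,
                speaking_turns=turns,
            )
        )
    return metas


def default_config(**overrides) -> GeneratorConfig:
    """The package's default study conditions, with optional field overrides."""
    return replace(GeneratorConfig(), **overrides) if overrides else GeneratorConfig()
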