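"""Synthetic booster-channel plex generator with known ground truth.

The forward model mirrors the acquisition physics the processing chain is
built to invert:

* a log-normal proteome (per-protein abundance) digested into peptides with
  log-normal ionization efficiencies;
* pulse labeling: each sample channel carries a heavy/total fraction, either
  stated directly or derived from a linear short-pulse incorporation model
  ``fraction = synthesis_rate * labeling_time * attenuation`` (capped at 1);
  per-protein sensitivity exponents and per-condition attenuation factors
  modulate the channel-level fraction;
* the booster channel is fully heavy at a molar ratio taken from the design;
  the noise channel is fully light;
* MS1 detection: a (heavy or light) modification-state row is emitted only if
  its summed amount across all channels reaches the detection threshold —
  the mechanism by which the booster rescues low-stoichiometry heavy rows;
* co-isolation interference: each emitted row receives an added fraction of a
  per-row background amount, identical across channels, so the noise channel
  measures exactly what contaminates every other channel;
* multiplicative log-normal reporter noise with a configurable coefficient of
  variation.

Everything is reproducible from the seed: the ground truth and the
acquisition noise use separate child streams, so acquisition settings can be
varied (e.g. booster amount, detection threshold) without changing the
underlying proteome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .design import ChannelSpec, PlexDesign, TMT_CHANNELS
from .errors import ConfigError
from .io import HeavyTokenVocabulary, PeptideRecord, make_record, _write_rows, _fmt

_BODY_ALPHABET = "ACDEFGHILMNPQSTVWY"  # tryptic body, K/R reserved for the terminus


@dataclass(frozen=True)
class LabelingSpec:
    """Heavy/total labeling of one sample channel.

    Either ``fraction`` is given directly, or it is derived from the linear
    short-pulse model ``synthesis_rate_per_hour * labeling_time_hours``.
    ``attenuation`` (1 = unperturbed, 0 = fully blocked) scales incorporation
    and is what treatments act on.
    """

    fraction: float | None = None
    synthesis_rate_per_hour: float | None = None
    labeling_time_hours: float | None = None
    attenuation: float = 1.0

    def __post_init__(self) -> None:
        if self.fraction is None:
            if self.synthesis_rate_per_hour is None or self.labeling_time_hours is None:
                raise ConfigError(
                    "labeling needs either an explicit fraction or "
                    "(synthesis_rate_per_hour, labeling_time_hours)"
                )
            if self.synthesis_rate_per_hour < 0 or self.labeling_time_hours < 0:
                raise ConfigError("synthesis rate and labeling time must be >= 0")
        elif not 0.0 <= self.fraction <= 1.0:
            raise ConfigError(f"heavy fraction must lie in [0, 1] (got {self.fraction})")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ConfigError(f"attenuation must lie in [0, 1] (got {self.attenuation})")

    @property
    def base_fraction(self) -> float:
        if self.fraction is not None:
            return self.fraction
        return min(
            1.0, self.synthesis_rate_per_hour * self.labeling_time_hours
        )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic plex.

    Defaults are the standard study conditions: reporter CV 8%, co-isolation
    interference 3% of a per-row background, and a detection threshold
    auto-calibrated (when left ``None``) so that 20% of heavy rows would be
    emitted without a booster.
    """

    n_proteins: int = 300
    peptides_per_protein: tuple[float, float] = (3.0, 0.3)  # (mean, dispersion)
    abundance_log_mean: float = math.log(100.0)
    abundance_log_sigma: float = 0.6
    ionization_log_sigma: float = 0.4
    labeling: dict[str, LabelingSpec] = field(default_factory=dict)
    detection_threshold: float | None = None
    detection_pass_fraction: float = 0.2
    interference_fraction: float = 0.03
    interference_log_sigma: float = 0.5
    reporter_cv: float = 0.08
    sensitivity_sigma: float = 0.0
    condition_attenuation_range: dict[str, tuple[float, float]] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        mean, disp = self.peptides_per_protein
        if mean <= 0 or disp < 0:
            raise ConfigError("peptides_per_protein needs mean > 0 and dispersion >= 0")
        if self.abundance_log_sigma < 0 or self.ionization_log_sigma < 0:
            raise ConfigError("log-normal sigmas must be >= 0")
        if not 0.0 <= self.interference_fraction < 1.0:
            raise ConfigError("interference_fraction must lie in [0, 1)")
        if self.reporter_cv < 0:
            raise ConfigError("reporter_cv must be >= 0")
        if self.detection_threshold is not None and self.detection_threshold < 0:
            raise ConfigError("detection_threshold must be >= 0")
        if not 0.0 < self.detection_pass_fraction <= 1.0:
            raise ConfigError("detection_pass_fraction must lie in (0, 1]")
        for cond, (lo, hi) in self.condition_attenuation_range.items():
            if not 0.0 <= lo <= hi <= 1.0:
                raise ConfigError(
                    f"attenuation range for condition {cond!r} must satisfy "
                    f"0 <= lo <= hi <= 1"
                )


@dataclass
class GroundTruth:
    """Simulator-side truth: proteome, peptides, and per-channel heavy fractions."""

    protein_ids: list[str]
    abundance: np.ndarray  # (P,)
    sensitivity: np.ndarray  # (P,) exponent on channel attenuation
    condition_multipliers: dict[str, np.ndarray]  # condition -> (P,)
    peptide_sequences: list[str]
    peptide_protein_index: np.ndarray  # (N,) int
    ionization: np.ndarray  # (N,)
    sample_channel_ids: list[str]
    heavy_fraction: np.ndarray  # (n_sample_channels, P)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_peptides(self) -> int:
        return len(self.peptide_sequences)

    def peptide_amount(self) -> np.ndarray:
        """Per-peptide precursor amount: protein abundance x ionization."""
        return self.abundance[self.peptide_protein_index] * self.ionization

    def heavy_fraction_for(self, channel_id: str) -> np.ndarray:
        """Per-protein true heavy fraction in one sample channel."""
        idx = self.sample_channel_ids.index(channel_id)
        return self.heavy_fraction[idx]


def _rng_pair(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    truth_ss, acq_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(truth_ss), np.random.default_rng(acq_ss)


def _draw_peptide_counts(
    rng: np.random.Generator, n: int, mean: float, dispersion: float
) -> np.ndarray:
    if dispersion == 0:
        counts = rng.poisson(mean, size=n)
    else:
        r = 1.0 / dispersion
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p, size=n)
    return np.maximum(counts, 1)


def _random_sequences(rng: np.random.Generator, n: int) -> list[str]:
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        length = int(rng.integers(7, 18))
        body = "".join(
            _BODY_ALPHABET[i] for i in rng.integers(0, len(_BODY_ALPHABET), size=length)
        )
        seq = body + ("K" if rng.integers(0, 2) == 0 else "R")
        if seq not in seen:
            seen.add(seq)
            seqs.append(seq)
    return seqs


def build_ground_truth(config: SimulationConfig, design: PlexDesign) -> GroundTruth:
    """Draw the proteome, peptides, and per-channel heavy fractions.

    Reproducible from ``config.seed``; protein abundances and peptide
    ionization factors are log-normal, heavy fractions follow the labeling
    spec per sample channel modulated by per-protein sensitivity and
    per-condition attenuation multipliers.
    """
    sample_ids = [c.channel_id for c in design.sample_channels]
    for ch in sample_ids:
        if ch not in config.labeling:
            raise ConfigError(f"no labeling spec for sample channel {ch!r}")
    rng, _ = _rng_pair(config.seed)
    P = config.n_proteins
    abundance = rng.lognormal(config.abundance_log_mean, config.abundance_log_sigma, P)
    sensitivity = (
        np.exp(rng.normal(0.0, config.sensitivity_sigma, P))
        if config.sensitivity_sigma > 0
        else np.ones(P)
    )
    multipliers: dict[str, np.ndarray] = {}
    for cond in design.conditions:
        if cond in config.condition_attenuation_range:
            lo, hi = config.condition_attenuation_range[cond]
            multipliers[cond] = rng.uniform(lo, hi, P)
    counts = _draw_peptide_counts(rng, P, *config.peptides_per_protein)
    protein_index = np.repeat(np.arange(P), counts)
    N = int(protein_index.size)
    ionization = rng.lognormal(0.0, config.ionization_log_sigma, N)
    sequences = _random_sequences(rng, N)

    heavy = np.zeros((len(sample_ids), P))
    for i, ch in enumerate(design.sample_channels):
        spec = config.labeling[ch.channel_id]
        a = spec.attenuation
        per_protein = np.full(P, a) if a in (0.0, 1.0) else a**sensitivity
        if a == 1.0:
            per_protein = np.ones(P)
        mult = multipliers.get(ch.condition, None)
        h = spec.base_fraction * per_protein
        if mult is not None:
            h = h * mult
        heavy[i] = np.clip(h, 0.0, 1.0)

    return GroundTruth(
        protein_ids=[f"P{i + 1:05d}" for i in range(P)],
        abundance=abundance,
        sensitivity=sensitivity,
        condition_multipliers=multipliers,
        peptide_sequences=sequences,
        peptide_protein_index=protein_index,
        ionization=ionization,
        sample_channel_ids=sample_ids,
        heavy_fraction=heavy,
    )


def simulate_labeling(
    truth: GroundTruth, design: PlexDesign, channel_id: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-peptide (light_amount, heavy_amount) for one channel.

    Sample channels split the precursor amount by the true heavy fraction;
    the booster is fully heavy scaled by its molar ratio; the noise channel is
    fully light.
    """
    amount = truth.peptide_amount()
    spec = next(c for c in design.channels if c.channel_id == channel_id)
    if spec.role == "booster":
        ratio = spec.booster_molar_ratio
        return np.zeros_like(amount), ratio * amount
    if spec.role == "noise":
        return amount.copy(), np.zeros_like(amount)
    h = truth.heavy_fraction_for(channel_id)[truth.peptide_protein_index]
    heavy = amount * h
    return amount - heavy, heavy


def calibrate_detection_threshold(
    truth: GroundTruth, design: PlexDesign, pass_fraction: float = 0.2
) -> float:
    """Detection threshold at which *pass_fraction* of heavy rows would be
    emitted without any booster (summed over sample channels only)."""
    amount = truth.peptide_amount()
    h = truth.heavy_fraction[:, truth.peptide_protein_index]  # (S, N)
    no_booster_sums = (amount[None, :] * h).sum(axis=0)
    n = no_booster_sums.size
    k = int(math.floor(pass_fraction * n))  # rows that should pass
    if k <= 0:
        return float(no_booster_sums.max()) * (1.0 + 1e-9)
    # the k-th largest sum: exactly k rows satisfy sum >= threshold
    return float(np.sort(no_booster_sums)[n - k])


def _heavy_modifications(sequence: str) -> str:
    if sequence.endswith("K"):
        return f"TMT6(N-Term); TMT6+K8(K{len(sequence)})"
    return f"TMT6(N-Term); Arg10(R{len(sequence)})"


def simulate_acquisition(
    truth: GroundTruth, design: PlexDesign, config: SimulationConfig
) -> list[PeptideRecord]:
    """Emit the peptide table: detection, interference, and reporter noise.

    Per peptide, up to two modification-state rows (heavy, light) are emitted.
    A row appears only if its plex-summed amount reaches the detection
    threshold. Each emitted row's channels receive
    ``(amount + interference_fraction * background) * noise`` where the per-row
    background is log-normal around the typical peptide amount (identical
    across channels, so the noise channel measures it) and ``noise`` is
    multiplicative log-normal with CV ``reporter_cv``.
    """
    _, rng = _rng_pair(config.seed)
    channels = list(design.channel_ids)
    amount = truth.peptide_amount()
    N = truth.n_peptides
    C = len(channels)

    light = np.empty((C, N))
    heavy = np.empty((C, N))
    for j, ch in enumerate(channels):
        light[j], heavy[j] = simulate_labeling(truth, design, ch)

    threshold = config.detection_threshold
    if threshold is None:
        threshold = calibrate_detection_threshold(
            truth, design, config.detection_pass_fraction
        )
    heavy_keep = heavy.sum(axis=0) >= threshold
    light_keep = light.sum(axis=0) >= threshold

    # Fixed draw order (independent of emission) keeps tables comparable
    # across acquisition settings at the same seed.
    scale = float(np.median(amount))
    sig_b = config.interference_log_sigma
    background = rng.lognormal(
        math.log(scale) - 0.5 * sig_b**2, sig_b, size=(2, N)
    )
    if config.reporter_cv > 0:
        sig_e = math.sqrt(math.log(1.0 + config.reporter_cv**2))
        eps = rng.lognormal(-0.5 * sig_e**2, sig_e, size=(2, N, C))
    else:
        eps = np.ones((2, N, C))

    f = config.interference_fraction
    heavy_int = (heavy.T + f * background[0][:, None]) * eps[0]  # (N, C)
    light_int = (light.T + f * background[1][:, None]) * eps[1]

    vocab = HeavyTokenVocabulary()
    records: list[PeptideRecord] = []
    for i in range(N):
        acc = truth.protein_ids[truth.peptide_protein_index[i]]
        seq = truth.peptide_sequences[i]
        if heavy_keep[i]:
            records.append(
                make_record(
                    sequence=seq,
                    modifications=_heavy_modifications(seq),
                    master_accession=acc,
                    intensities={ch: float(heavy_int[i, j]) for j, ch in enumerate(channels)},
                    vocab=vocab,
                )
            )
        if light_keep[i]:
            records.append(
                make_record(
                    sequence=seq,
                    modifications="TMT6(N-Term)",
                    master_accession=acc,
                    intensities={ch: float(light_int[i, j]) for j, ch in enumerate(channels)},
                    vocab=vocab,
                )
            )
    return records


def simulate_plex(
    design: PlexDesign, config: SimulationConfig
) -> tuple[list[PeptideRecord], GroundTruth]:
    """Convenience: ground truth plus emitted peptide table in one call."""
    truth = build_ground_truth(config, design)
    return simulate_acquisition(truth, design, config), truth


def write_ground_truth(
    truth: GroundTruth, design: PlexDesign, path: str | Path
) -> None:
    """Write per-protein truth: abundance, sensitivity, condition multipliers,
    and the true heavy fraction per sample channel."""
    mult_conds = sorted(truth.condition_multipliers)
    header = (
        ["protein_id", "abundance", "sensitivity"]
        + [f"attenuation_{c}" for c in mult_conds]
        + [f"heavy_fraction_{ch}" for ch in truth.sample_channel_ids]
    )

    def rows():
        for p, pid in enumerate(truth.protein_ids):
            yield (
                [pid, _fmt(float(truth.abundance[p])), _fmt(float(truth.sensitivity[p]))]
                + [_fmt(float(truth.condition_multipliers[c][p])) for c in mult_conds]
                + [_fmt(float(truth.heavy_fraction[i, p]))
                   for i in range(len(truth.sample_channel_ids))]
            )

    _write_rows(path, header, rows())


# ---------------------------------------------------------------------------
# scenario presets mirroring the printed experiment layouts

#: Heavy/total fractions of the low dilution series (0.1%-10% H/T).
DILUTION_LOW_FRACTIONS = (0.001, 0.0025, 0.005, 0.01, 0.025, 0.05, 0.075, 0.10)
#: Heavy/total fractions of the wide dilution series (2.5%-80% H/T).
DILUTION_WIDE_FRACTIONS = (0.025, 0.05, 0.10, 0.20, 0.30, 0.40, 0.60, 0.80)
#: Labeling times (hours) of the incorporation time course (15-120 min).
TIME_COURSE_HOURS = (0.25, 0.5, 1.0, 1.5, 2.0)
#: Default linear incorporation rate: fraction of the proteome newly
#: synthesized per hour of pulse (0.05/h -> 10% heavy after a 2 h pulse).
DEFAULT_SYNTHESIS_RATE = 0.05
#: Doses (arbitrary concentration units) of the global-inhibitor titration.
CHX_DOSES = (0.5, 2.0, 8.0, 32.0, 128.0)
#: Half-maximal inhibitory concentration of the titration model.
CHX_IC50 = 2.0
#: Matched global attenuation levels of the two-agent stress titration.
STRESS_LEVELS = (0.75, 0.45, 0.2)

PRESET_NAMES = (
    "dilution_low",
    "dilution_wide",
    "time_course",
    "booster_titration",
    "chx_titration",
    "stress_titration",
)


def _design(plex_id: str, samples: list[ChannelSpec], booster_ratio: float) -> PlexDesign:
    n = len(samples) + 2
    ids = list(TMT_CHANNELS[:n])
    channels = [ChannelSpec(channel_id=ids[0], role="noise")]
    for i, s in enumerate(samples, start=1):
        channels.append(replace(s, channel_id=ids[i]))
    channels.append(
        ChannelSpec(channel_id=ids[-1], role="booster", booster_molar_ratio=booster_ratio)
    )
    return PlexDesign(plex_id=plex_id, channels=tuple(channels))


def _dilution_preset(
    plex_id: str, fractions: Sequence[float], seed: int, booster_ratio: float
) -> tuple[PlexDesign, SimulationConfig]:
    samples = [
        ChannelSpec(
            channel_id="?", role="sample",
            condition=f"ht_{100 * f:g}pct", replicate=1,
        )
        for f in fractions
    ]
    design = _design(plex_id, samples, booster_ratio)
    labeling = {
        c.channel_id: LabelingSpec(fraction=f)
        for c, f in zip(design.sample_channels, fractions)
    }
    config = SimulationConfig(n_proteins=400, labeling=labeling, seed=seed)
    return design, config


def scenario_preset(
    name: str, seed: int, booster_molar_ratio: float = 2.0
) -> tuple[PlexDesign, SimulationConfig]:
    """Ready-to-run (design, config) pairs for the standard experiment layouts.

    ``dilution_low``/``dilution_wide``: 10-plex heavy/light mixing series at
    0.1-10% and 2.5-80% H/T. ``time_course``: 15-120 min pulse labeling, two
    replicates per time point. ``booster_titration``: duplicate 5%/10% mixes
    with a configurable booster amount. ``chx_titration``: global-inhibitor
    dose series. ``stress_titration``: two agents titrated to matched global
    attenuation levels with shared per-protein sensitivities.
    """
    if name == "dilution_low":
        return _dilution_preset("dilution_low", DILUTION_LOW_FRACTIONS, seed,
                                booster_molar_ratio)
    if name == "dilution_wide":
        return _dilution_preset("dilution_wide", DILUTION_WIDE_FRACTIONS, seed,
                                booster_molar_ratio)
    if name == "time_course":
        samples = [
            ChannelSpec(
                channel_id="?", role="sample",
                condition=f"t{int(60 * t)}min", replicate=rep,
            )
            for t in TIME_COURSE_HOURS
            for rep in (1, 2)
        ]
        design = _design("time_course", samples, booster_molar_ratio)
        labeling = {}
        i = 0
        for t in TIME_COURSE_HOURS:
            for _rep in (1, 2):
                labeling[design.sample_channels[i].channel_id] = LabelingSpec(
                    synthesis_rate_per_hour=DEFAULT_SYNTHESIS_RATE,
                    labeling_time_hours=t,
                )
                i += 1
        config = SimulationConfig(n_proteins=400, labeling=labeling, seed=seed)
        return design, config
    if name == "booster_titration":
        samples = [
            ChannelSpec(channel_id="?", role="sample", condition="ht_5pct", replicate=1),
            ChannelSpec(channel_id="?", role="sample", condition="ht_5pct", replicate=2),
            ChannelSpec(channel_id="?", role="sample", condition="ht_10pct", replicate=1),
            ChannelSpec(channel_id="?", role="sample", condition="ht_10pct", replicate=2),
        ]
        design = _design("booster_titration", samples, booster_molar_ratio)
        fractions = (0.05, 0.05, 0.10, 0.10)
        labeling = {
            c.channel_id: LabelingSpec(fraction=f)
            for c, f in zip(design.sample_channels, fractions)
        }
        config = SimulationConfig(n_proteins=400, labeling=labeling, seed=seed)
        return design, config
    if name == "chx_titration":
        conditions = ["control"] + [f"chx_{d:g}" for d in CHX_DOSES]
        attenuations = [1.0] + [1.0 / (1.0 + d / CHX_IC50) for d in CHX_DOSES]
        samples = [
            ChannelSpec(channel_id="?", role="sample", condition=c, replicate=1)
            for c in conditions
        ]
        design = _design("chx_titration", samples, booster_molar_ratio)
        labeling = {
            ch.channel_id: LabelingSpec(
                synthesis_rate_per_hour=DEFAULT_SYNTHESIS_RATE,
                labeling_time_hours=2.0,
                attenuation=a,
            )
            for ch, a in zip(design.sample_channels, attenuations)
        }
        config = SimulationConfig(n_proteins=400, labeling=labeling, seed=seed)
        return design, config
    if name == "stress_titration":
        samples = []
        labeling_specs = []
        for agent in ("agentA", "agentB"):
            for level, a in zip(("low", "mid", "high"), STRESS_LEVELS):
                samples.append(
                    ChannelSpec(
                        channel_id="?", role="sample",
                        condition=f"{agent}_{level}", replicate=1,
                    )
                )
                labeling_specs.append(a)
        design = _design("stress_titration", samples, booster_molar_ratio)
        labeling = {
            ch.channel_id: LabelingSpec(
                synthesis_rate_per_hour=DEFAULT_SYNTHESIS_RATE,
                labeling_time_hours=2.0,
                attenuation=a,
            )
            for ch, a in zip(design.sample_channels, labeling_specs)
        }
        config = SimulationConfig(
            n_proteins=300, labeling=labeling, sensitivity_sigma=0.4, seed=seed
        )
        return design, config
    raise ConfigError(
        f"unknown scenario {name!r}; valid names: {', '.join(PRESET_NAMES)}"
    )


def two_condition_preset(
    seed: int,
    n_proteins: int = 1000,
    n_replicates: int = 3,
    attenuation_range: tuple[float, float] = (0.1, 1.0),
    booster_molar_ratio: float = 2.0,
) -> tuple[PlexDesign, SimulationConfig]:
    """Control-vs-treated contrast with per-protein attenuation ground truth.

    Treated channels share the control labeling kinetics but each protein's
    incorporation is scaled by its own attenuation factor drawn uniformly from
    *attenuation_range* — the quantity a differential contrast estimates.
    """
    samples = [
        ChannelSpec(channel_id="?", role="sample", condition="control", replicate=r)
        for r in range(1, n_replicates + 1)
    ] + [
        ChannelSpec(channel_id="?", role="sample", condition="treated", replicate=r)
        for r in range(1, n_replicates + 1)
    ]
    design = _design("contrast", samples, booster_molar_ratio)
    labeling = {
        ch.channel_id: LabelingSpec(
            synthesis_rate_per_hour=DEFAULT_SYNTHESIS_RATE, labeling_time_hours=2.0
        )
        for ch in design.sample_channels
    }
    config = SimulationConfig(
        n_proteins=n_proteins,
        labeling=labeling,
        condition_attenuation_range={"treated": attenuation_range},
        seed=seed,
    )
    return design, config
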