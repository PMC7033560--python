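"""The booster-channel quantification engine.

The processing chain turns a peptide-level reporter-ion table into per-protein
relative translation rates:

1. ``sum_normalize``      — scale every channel to the lowest channel's total
                            intensity (equimolar pooling correction);
2. ``collapse_heavy``     — average all heavy modification states of a peptide
                            sequence into one per-channel vector;
3. ``subtract_baseline``  — subtract the noise channel (co-isolation
                            interference) from every other channel, clamping
                            negatives to zero;
4. ``relative_to_booster``— divide sample channels by the booster channel,
                            yielding dimensionless relative translation;
5. ``rollup_proteins``    — per-protein median over peptide sequences.

Relative translation is comparable across channels and — because the booster
is an absolute reference — across separate LC-MS runs (``merge_runs``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Sequence

import numpy as np

from .design import PlexDesign
from .errors import DesignError, NormalizationError
from .io import PeptideRecord, filter_records

logger = logging.getLogger("meprod")

SHARED_ACCESSION = "shared"


@dataclass
class HeavyPeptideProfile:
    """Per-(sequence, protein) averaged heavy-state intensity vector."""

    sequence: str
    master_accession: str
    heavy_intensity: dict[str, float]
    n_states: int


@dataclass
class ProteinTranslationProfile:
    """Per-protein relative translation (fraction of booster signal) per sample."""

    master_accession: str
    relative_translation: dict[str, float]
    n_peptides: int
    plex_id: str


@dataclass
class GlobalTranslationSummary:
    """Per-channel medians of relative translation and per-condition summary."""

    per_channel_median: dict[str, float]
    relative_to_control: dict[str, float] | None
    control_condition: str | None
    level: str = "peptide"


@dataclass
class PipelineOptions:
    """Tunable switches of :func:`run_pipeline` (defaults match the standard chain)."""

    min_sn: float = 0.0
    exclude_booster_from_norm: bool = False
    baseline_subtraction: bool = True
    global_level: str = "peptide"  # or "protein"
    control_condition: str | None = None


@dataclass
class PipelineResult:
    heavy_peptides: list[HeavyPeptideProfile]
    proteins: list[ProteinTranslationProfile]
    global_summary: GlobalTranslationSummary | None
    counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stages


def sum_normalize(
    records: Sequence[PeptideRecord],
    design: PlexDesign,
    exclude_booster_from_norm: bool = False,
) -> list[PeptideRecord]:
    """Normalize each channel to the lowest channel's total intensity.

    Every channel is multiplied by ``min(total) / total(channel)`` so that all
    totals end up equal to the grand minimum. With
    ``exclude_booster_from_norm`` the booster channel keeps its molar scale and
    is excluded from the minimum; sample and noise channels are still equalised.
    """
    channels = list(design.channel_ids)
    if exclude_booster_from_norm:
        channels = [c for c in channels if c != design.booster.channel_id]
    totals = {ch: 0.0 for ch in channels}
    for r in records:
        for ch in channels:
            totals[ch] += r.intensities[ch]
    for ch, tot in totals.items():
        if tot <= 0:
            raise NormalizationError(
                f"channel {ch!r} has zero total intensity; cannot sum-normalize"
            )
    lowest = min(totals.values())
    factors = {ch: lowest / tot for ch, tot in totals.items()}
    logger.info(
        "sum normalization factors: %s",
        {ch: round(f, 6) for ch, f in factors.items()},
    )
    return [r.scaled(factors) for r in records]


def collapse_heavy(records: Sequence[PeptideRecord]) -> list[HeavyPeptideProfile]:
    """Average all heavy modification states per (sequence, protein).

    Sequences observed only as light states yield no profile; the unweighted
    arithmetic mean is taken per channel across heavy states.
    """
    groups: dict[tuple[str, str], list[PeptideRecord]] = {}
    for r in records:
        if not r.is_heavy:
            continue
        groups.setdefault((r.sequence, r.master_accession), []).append(r)
    profiles = []
    for (seq, acc), members in groups.items():
        n = len(members)
        channels = members[0].intensities.keys()
        mean = {ch: sum(m.intensities[ch] for m in members) / n for ch in channels}
        profiles.append(
            HeavyPeptideProfile(
                sequence=seq, master_accession=acc, heavy_intensity=mean, n_states=n
            )
        )
    return profiles


def subtract_baseline(
    profiles: Sequence[HeavyPeptideProfile], design: PlexDesign
) -> list[HeavyPeptideProfile]:
    """Subtract the noise-channel value per peptide; clamp negatives to zero.

    The noise channel carries no genuine heavy signal, so whatever it measures
    is co-isolation interference common to all channels. It is removed from
    the intensity map afterwards.
    """
    noise_id = design.noise.channel_id
    out = []
    for p in profiles:
        base = p.heavy_intensity[noise_id]
        sub = {
            ch: max(v - base, 0.0)
            for ch, v in p.heavy_intensity.items()
            if ch != noise_id
        }
        out.append(
            HeavyPeptideProfile(
                sequence=p.sequence,
                master_accession=p.master_accession,
                heavy_intensity=sub,
                n_states=p.n_states,
            )
        )
    return out


def drop_noise_channel(
    profiles: Sequence[HeavyPeptideProfile], design: PlexDesign
) -> list[HeavyPeptideProfile]:
    """Remove the noise channel without subtracting it (diagnostic variant)."""
    noise_id = design.noise.channel_id
    return [
        HeavyPeptideProfile(
            sequence=p.sequence,
            master_accession=p.master_accession,
            heavy_intensity={
                ch: v for ch, v in p.heavy_intensity.items() if ch != noise_id
            },
            n_states=p.n_states,
        )
        for p in profiles
    ]


def relative_to_booster(
    profiles: Sequence[HeavyPeptideProfile], design: PlexDesign
) -> list[HeavyPeptideProfile]:
    """Divide every sample channel by the booster channel value.

    Peptides whose booster signal is zero after baseline subtraction have an
    undefined ratio; they are dropped (and counted in the log), not imputed.
    """
    booster_id = design.booster.channel_id
    out = []
    dropped = 0
    for p in profiles:
        denom = p.heavy_intensity[booster_id]
        if denom <= 0:
            dropped += 1
            continue
        ratios = {
            ch: v / denom for ch, v in p.heavy_intensity.items() if ch != booster_id
        }
        out.append(
            HeavyPeptideProfile(
                sequence=p.sequence,
                master_accession=p.master_accession,
                heavy_intensity=ratios,
                n_states=p.n_states,
            )
        )
    if dropped:
        logger.info("dropped %d peptide profiles with zero booster signal", dropped)
    return out


def rollup_proteins(
    profiles: Sequence[HeavyPeptideProfile], plex_id: str = ""
) -> list[ProteinTranslationProfile]:
    """Per-protein, per-channel median over peptide sequences.

    Peptides mapping to more than one protein group (``master_accession ==
    "shared"``) are excluded. The even-count median is the mean of the two
    middle values.
    """
    groups: dict[str, list[HeavyPeptideProfile]] = {}
    for p in profiles:
        if p.master_accession == SHARED_ACCESSION:
            continue
        groups.setdefault(p.master_accession, []).append(p)
    out = []
    for acc, members in groups.items():
        channels = members[0].heavy_intensity.keys()
        med = {
            ch: float(np.median([m.heavy_intensity[ch] for m in members]))
            for ch in channels
        }
        out.append(
            ProteinTranslationProfile(
                master_accession=acc,
                relative_translation=med,
                n_peptides=len(members),
                plex_id=plex_id,
            )
        )
    return out


def global_translation(
    profiles: Sequence[HeavyPeptideProfile] | Sequence[ProteinTranslationProfile],
    design: PlexDesign,
    control_condition: str | None = None,
    level: str = "peptide",
) -> GlobalTranslationSummary:
    """Median relative translation per sample channel plus per-condition summary.

    Accepts booster-relative peptide profiles (default) or protein profiles.
    Per condition, the mean of its replicate channel medians is divided by the
    control condition's mean.
    """
    if not profiles:
        return GlobalTranslationSummary(
            per_channel_median={},
            relative_to_control=None,
            control_condition=control_condition,
            level=level,
        )
    values = [
        getattr(p, "heavy_intensity", None) or getattr(p, "relative_translation")
        for p in profiles
    ]
    medians = {
        ch.channel_id: float(median(v[ch.channel_id] for v in values))
        for ch in design.sample_channels
    }
    rel = None
    if control_condition is not None:
        if control_condition not in design.conditions:
            raise DesignError(
                f"control condition {control_condition!r} not present in design "
                f"(conditions: {list(design.conditions)})"
            )
        cond_means = {
            cond: float(
                np.mean([medians[c.channel_id] for c in design.channels_for(cond)])
            )
            for cond in design.conditions
        }
        control_mean = cond_means[control_condition]
        if control_mean <= 0:
            raise NormalizationError(
                f"control condition {control_condition!r} has non-positive mean "
                f"median translation; cannot express conditions relative to it"
            )
        rel = {cond: m / control_mean for cond, m in cond_means.items()}
    return GlobalTranslationSummary(
        per_channel_median=medians,
        relative_to_control=rel,
        control_condition=control_condition,
        level=level,
    )


def merge_runs(
    profile_sets: Sequence[Sequence[ProteinTranslationProfile]],
):
    """Outer-join protein profiles from several plexes on accession.

    Booster-relative values are carried unchanged — the booster is the common
    absolute reference, so no cross-run normalization is applied. Columns are
    labelled ``<plex_id>:<channel_id>``; a protein absent from a plex keeps
    missing (NaN) cells, never zeros.
    """
    import pandas as pd

    seen_plex: set[str] = set()
    columns: list[str] = []
    data: dict[str, dict[str, float]] = {}
    for profiles in profile_sets:
        if not profiles:
            continue
        plex_id = profiles[0].plex_id
        if plex_id in seen_plex:
            raise DesignError(f"plex id {plex_id!r} passed more than once to merge_runs")
        seen_plex.add(plex_id)
        for p in profiles:
            for ch, v in p.relative_translation.items():
                label = f"{plex_id}:{ch}"
                if label not in data:
                    if label in columns:
                        raise DesignError(f"duplicate sample label {label!r}")
                    columns.append(label)
                    data[label] = {}
                if p.master_accession in data[label]:
                    raise DesignError(
                        f"duplicate accession {p.master_accession!r} in plex {plex_id!r}"
                    )
                data[label][p.master_accession] = v
    frame = pd.DataFrame(data, columns=columns)
    frame.index.name = "master_accession"
    return frame.sort_index()


# ---------------------------------------------------------------------------
# composition


def run_pipeline(
    records: Sequence[PeptideRecord],
    design: PlexDesign,
    options: PipelineOptions | None = None,
) -> PipelineResult:
    """Run the full chain: filter → normalize → collapse → baseline → booster → rollup."""
    options = options or PipelineOptions()
    counts = {"input": len(records)}
    if not records:
        logger.warning("run_pipeline called with an empty record list")
        return PipelineResult(
            heavy_peptides=[],
            proteins=[],
            global_summary=None,
            counts=counts,
        )
    records = filter_records(records, options.min_sn)
    counts["after_sn_filter"] = len(records)
    records = sum_normalize(
        records, design, exclude_booster_from_norm=options.exclude_booster_from_norm
    )
    profiles = collapse_heavy(records)
    counts["heavy_peptide_profiles"] = len(profiles)
    if options.baseline_subtraction:
        profiles = subtract_baseline(profiles, design)
    else:
        profiles = drop_noise_channel(profiles, design)
    profiles = relative_to_booster(profiles, design)
    counts["after_booster_ratio"] = len(profiles)
    proteins = rollup_proteins(profiles, plex_id=design.plex_id)
    counts["proteins"] = len(proteins)
    if options.global_level == "protein":
        summary = global_translation(
            proteins, design, options.control_condition, level="protein"
        )
    else:
        summary = global_translation(
            profiles, design, options.control_condition, level="peptide"
        )
    logger.info("pipeline stage counts: %s", counts)
    return PipelineResult(
        heavy_peptides=profiles,
        proteins=proteins,
        global_summary=summary,
        counts=counts,
    )
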