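"""Peptide-table reading, record-level filters, and tabular outputs.

The input dialect is a UTF-8, tab-separated table with one row per peptide
modification state (the shape of a search-engine peptide export): columns
``sequence``, ``modifications``, ``master_accession``, optional ``accessions``
(semicolon-separated), optional ``sn`` (mean reporter signal-to-noise), and one
reporter-intensity column per designed channel. Intensity headers may be the
bare channel id (``126``, ``127N``, ...) or the ``Abundance: 126`` alias.

A peptide row counts as *heavy* when its modification set contains at least
one heavy-label token (``K8``, ``Arg10``, ``TMT6+K8``, ...). Tokens may carry a
position suffix, e.g. ``TMT6+K8(K8)``; matching ignores the suffix.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .design import PlexDesign
from .errors import FormatError, MeprodError

logger = logging.getLogger("meprod")

#: Heavy-label modification tokens recognised by default. Covers SILAC heavy
#: lysine/arginine in both search-engine spellings and the TMT+heavy-lysine
#: combination tag.
DEFAULT_HEAVY_TOKENS = frozenset(
    {"K8", "Arg10", "TMT6+K8", "Label:13C(6)15N(2)", "Label:13C(6)15N(4)"}
)

_POSITION_SUFFIX = re.compile(r"\([^()]*\)$")


@dataclass(frozen=True)
class HeavyTokenVocabulary:
    """The set of modification tokens that mark a peptide state as heavy."""

    tokens: frozenset[str] = DEFAULT_HEAVY_TOKENS

    def __post_init__(self) -> None:
        if not self.tokens:
            raise MeprodError("heavy-token vocabulary must be non-empty")
        object.__setattr__(self, "tokens", frozenset(self.tokens))

    def matches(self, modification_tokens: Iterable[str]) -> bool:
        """True if any token (raw or with its position suffix stripped) is heavy."""
        for tok in modification_tokens:
            tok = tok.strip()
            if tok in self.tokens:
                return True
            if _POSITION_SUFFIX.sub("", tok).strip() in self.tokens:
                return True
        return False


def parse_modifications(text: str) -> tuple[str, ...]:
    """Split a ``"Oxidation(M3); TMT6+K8(K8)"``-style string into tokens."""
    if not text or not text.strip():
        return ()
    return tuple(t.strip() for t in text.split(";") if t.strip())


@dataclass
class PeptideRecord:
    """One peptide modification-state row with per-channel reporter intensities.

    ``was_missing`` records channels whose intensity cell was blank in the
    source table; such cells are stored as 0.0.
    """

    sequence: str
    modifications: tuple[str, ...]
    master_accession: str
    intensities: dict[str, float]
    accessions: frozenset[str] = frozenset()
    sn: float | None = None
    was_missing: frozenset[str] = frozenset()
    is_heavy: bool = False

    def __post_init__(self) -> None:
        if not self.accessions:
            self.accessions = frozenset({self.master_accession})
        for ch, v in self.intensities.items():
            if not (v >= 0) or v != v or v in (float("inf"),):
                raise FormatError(
                    f"peptide {self.sequence!r}: intensity for channel {ch!r} "
                    f"must be a finite non-negative number (got {v!r})"
                )

    def scaled(self, factors: dict[str, float]) -> "PeptideRecord":
        """Copy with each channel intensity multiplied by its factor."""
        new = {ch: v * factors.get(ch, 1.0) for ch, v in self.intensities.items()}
        return replace(self, intensities=new)


def make_record(
    *,
    sequence: str,
    modifications: Sequence[str] | str,
    master_accession: str,
    intensities: dict[str, float],
    accessions: Iterable[str] | None = None,
    sn: float | None = None,
    was_missing: Iterable[str] = (),
    vocab: HeavyTokenVocabulary | None = None,
) -> PeptideRecord:
    """Build a :class:`PeptideRecord`, deriving ``is_heavy`` from *vocab*."""
    vocab = vocab or HeavyTokenVocabulary()
    if isinstance(modifications, str):
        mods = parse_modifications(modifications)
    else:
        mods = tuple(modifications)
    return PeptideRecord(
        sequence=sequence.upper(),
        modifications=mods,
        master_accession=master_accession,
        intensities=dict(intensities),
        accessions=frozenset(accessions) if accessions else frozenset(),
        sn=sn,
        was_missing=frozenset(was_missing),
        is_heavy=vocab.matches(mods),
    )


# ---------------------------------------------------------------------------
# reading


def _resolve_intensity_columns(
    columns: Sequence[str], design: PlexDesign
) -> dict[str, str]:
    """Map each designed channel id to its table column (bare id or alias)."""
    mapping: dict[str, str] = {}
    for ch in design.channel_ids:
        if ch in columns:
            mapping[ch] = ch
        elif f"Abundance: {ch}" in columns:
            mapping[ch] = f"Abundance: {ch}"
        else:
            raise FormatError(
                f"peptide table lacks an intensity column for channel {ch!r} "
                f"(expected {ch!r} or 'Abundance: {ch}')"
            )
    return mapping


def read_peptide_table(
    path: str | Path,
    design: PlexDesign,
    vocab: HeavyTokenVocabulary | None = None,
) -> list[PeptideRecord]:
    """Read a TSV peptide export into records for *design*'s channels.

    Blank intensity cells become 0.0 and are flagged in ``was_missing``;
    non-numeric cells raise :class:`FormatError` with the offending data row
    number (1-based, excluding the header).
    """
    vocab = vocab or HeavyTokenVocabulary()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for required in ("sequence", "modifications", "master_accession"):
        if required not in df.columns:
            raise FormatError(f"peptide table lacks required column {required!r}")
    colmap = _resolve_intensity_columns(list(df.columns), design)

    records: list[PeptideRecord] = []
    has_acc = "accessions" in df.columns
    has_sn = "sn" in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        intensities: dict[str, float] = {}
        missing: list[str] = []
        for ch, col in colmap.items():
            cell = rowd[col].strip()
            if cell == "":
                intensities[ch] = 0.0
                missing.append(ch)
            else:
                try:
                    intensities[ch] = float(cell)
                except ValueError:
                    raise FormatError(
                        f"non-numeric intensity {cell!r} for channel {ch!r} "
                        f"in row {i}"
                    ) from None
        sn_val: float | None = None
        if has_sn and rowd["sn"].strip():
            try:
                sn_val = float(rowd["sn"])
            except ValueError:
                raise FormatError(
                    f"non-numeric sn value {rowd['sn']!r} in row {i}"
                ) from None
        accessions = (
            frozenset(a.strip() for a in rowd["accessions"].split(";") if a.strip())
            if has_acc and rowd["accessions"].strip()
            else None
        )
        records.append(
            make_record(
                sequence=rowd["sequence"],
                modifications=rowd["modifications"],
                master_accession=rowd["master_accession"].strip(),
                intensities=intensities,
                accessions=accessions,
                sn=sn_val,
                was_missing=missing,
                vocab=vocab,
            )
        )
    logger.info("read %d peptide records from %s", len(records), path)
    return records


def filter_records(
    records: Sequence[PeptideRecord], min_sn: float
) -> list[PeptideRecord]:
    """Drop records below the signal-to-noise threshold (inclusive: sn >= min_sn
    is retained).

    Records without an ``sn`` value are retained only when ``min_sn == 0`` —
    interference that cannot be quantified cannot be vetted.
    """
    if min_sn < 0:
        raise MeprodError(f"min_sn must be >= 0 (got {min_sn})")
    if min_sn == 0:
        kept = list(records)
    else:
        kept = [r for r in records if r.sn is not None and r.sn >= min_sn]
    removed = len(records) - len(kept)
    if removed:
        logger.info("S/N filter (>= %g) removed %d of %d records", min_sn, removed, len(records))
    if records and not kept:
        logger.warning("S/N filter (>= %g) removed every record", min_sn)
    return kept


# ---------------------------------------------------------------------------
# writing

def _fmt(value: float | int | None) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)  # shortest round-trip representation
    return str(value)


def _write_rows(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            writer.writerow(row)


def write_peptide_table(
    records: Sequence[PeptideRecord], design: PlexDesign, path: str | Path
) -> None:
    """Write records as a TSV readable by :func:`read_peptide_table`.

    Rows are sorted by (accession, sequence, modifications); blank cells mark
    channels flagged ``was_missing`` so that a write/read round trip is the
    identity.
    """
    header = ["sequence", "modifications", "master_accession", "accessions", "sn"]
    header += list(design.channel_ids)
    ordered = sorted(
        records, key=lambda r: (r.master_accession, r.sequence, "; ".join(r.modifications))
    )

    def rows():
        for r in ordered:
            row = [
                r.sequence,
                "; ".join(r.modifications),
                r.master_accession,
                ";".join(sorted(r.accessions)),
                _fmt(r.sn),
            ]
            for ch in design.channel_ids:
                row.append("" if ch in r.was_missing else _fmt(r.intensities[ch]))
            yield row

    _write_rows(path, header, rows())


def write_heavy_peptide_table(profiles, design: PlexDesign, path: str | Path) -> None:
    """Write heavy peptide profiles: sequence, accession, n_states, channels."""
    present = []
    if profiles:
        keys = set(profiles[0].heavy_intensity)
        present = [ch for ch in design.channel_ids if ch in keys]
    header = ["sequence", "master_accession", "n_states"] + present
    ordered = sorted(profiles, key=lambda p: (p.master_accession, p.sequence))
    _write_rows(
        path,
        header,
        (
            [p.sequence, p.master_accession, p.n_states]
            + [_fmt(p.heavy_intensity[ch]) for ch in present]
            for p in ordered
        ),
    )


def write_protein_table(profiles, design: PlexDesign, path: str | Path) -> None:
    """Write protein translation profiles: accession, n_peptides, sample channels."""
    present = []
    if profiles:
        keys = set(profiles[0].relative_translation)
        present = [ch for ch in design.channel_ids if ch in keys]
    header = ["master_accession", "n_peptides"] + present
    ordered = sorted(profiles, key=lambda p: p.master_accession)
    _write_rows(
        path,
        header,
        (
            [p.master_accession, p.n_peptides]
            + [_fmt(p.relative_translation[ch]) for ch in present]
            for p in ordered
        ),
    )


def read_protein_table(path: str | Path) -> pd.DataFrame:
    """Read a protein table written by :func:`write_protein_table`.

    Returns a DataFrame indexed by accession; the ``n_peptides`` column is kept
    alongside the per-channel relative-translation columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={"master_accession": str})
    if "master_accession" not in df.columns:
        raise FormatError(f"protein table {path} lacks 'master_accession' column")
    return df.set_index("master_accession")


def write_global_table(summary, design: PlexDesign, path: str | Path) -> None:
    """Write the global-translation summary, one row per sample channel."""
    header = [
        "channel_id",
        "condition",
        "replicate",
        "median_relative_translation",
        "condition_relative_to_control",
    ]

    def rows():
        for ch in design.sample_channels:
            rel = (
                summary.relative_to_control.get(ch.condition)
                if summary.relative_to_control is not None
                else None
            )
            yield [
                ch.channel_id,
                ch.condition,
                ch.replicate,
                _fmt(summary.per_channel_median[ch.channel_id]),
                _fmt(rel),
            ]

    _write_rows(path, header, rows())


def write_stats_table(stats, path: str | Path) -> None:
    """Write differential-translation statistics (one row per protein)."""
    header = [
        "master_accession",
        "mean_control",
        "mean_treated",
        "log2fc",
        "t_stat",
        "p",
        "adj_p",
        "regulation_class",
    ]
    ordered = sorted(stats, key=lambda s: s.master_accession)
    _write_rows(
        path,
        header,
        (
            [
                s.master_accession,
                _fmt(s.mean_control),
                _fmt(s.mean_treated),
                _fmt(s.log2fc),
                _fmt(s.t_stat),
                _fmt(s.p),
                _fmt(s.adj_p),
                s.regulation_class,
            ]
            for s in ordered
        ),
    )


def write_linear_screen_table(results, path: str | Path) -> None:
    """Write per-protein dose-response linear-fit results."""
    header = [
        "master_accession",
        "slope",
        "intercept",
        "r_squared",
        "p_slope",
        "is_linear_responder",
    ]
    ordered = sorted(results, key=lambda r: r.master_accession)
    _write_rows(
        path,
        header,
        (
            [
                r.master_accession,
                _fmt(r.slope),
                _fmt(r.intercept),
                _fmt(r.r_squared),
                _fmt(r.p_slope),
                str(bool(r.is_linear_responder)),
            ]
            for r in ordered
        ),
    )
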