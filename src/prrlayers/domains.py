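"""Domain-architecture classification of pattern recognition receptors.

Sponges lack canonical TLRs but carry a diverse repertoire of innate immune
receptors that can be recognized from Pfam domain architectures alone:
TLR-like genes pairing an intracellular TIR domain with extracellular
immunoglobulin domains, bona fide NLRs combining a NACHT domain with
leucine-rich repeats, C-type lectin domain (CTLD) genes, scavenger receptor
cysteine-rich (SRCR) genes, and adhesion-type GPCRs with a seven-transmembrane
region optionally joined by a GPCR proteolytic site (GPS) motif.

This module implements that screen as an explicit, configurable rule engine:
each family is a predicate over the set of Pfam accessions observed on a
transcript plus its transmembrane-segment flag, and multi-family
architectures are resolved by a fixed precedence order.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

# Canonical Pfam accessions used by the default ruleset.
TIR = "PF01582"
IG_LIKE = "PF00047"
NACHT = "PF05729"
LRR = "PF13516"
GPS = "PF01825"
CTL = "PF00059"
SRCR_ACCESSIONS = frozenset({"PF00530", "PF15494"})
# "7TM" is a structural feature, not a single Pfam family; this set covers the
# rhodopsin, secretin and metabotropic-glutamate GPCR families plus the
# 7TM_GPCR_Srx/Srsx sensory families, and is override-able in the ruleset.
SEVEN_TM_ACCESSIONS = frozenset(
    {"PF00001", "PF00002", "PF00003", "PF10320", "PF10328"}
)

FAMILIES = (
    "TLR_like",
    "TIR_only",
    "NLR_bona_fide",
    "NACHT_only",
    "GPCR_GPS_7TM",
    "GPCR_7TM",
    "SRCR",
    "CTLD",
)

#: Precedence used to resolve transcripts whose architecture satisfies more
#: than one family rule (most specific composite architectures first).
DEFAULT_PRECEDENCE = FAMILIES


@dataclass(frozen=True)
class DomainHit:
    """One Pfam hit on a transcript, 1-based inclusive residue coordinates."""

    accession: str
    name: str
    start: int
    end: int
    evalue: float

    def validate(self) -> None:
        if self.start <= 0 or self.end <= 0:
            raise ValueError(
                f"non-positive coordinates ({self.start}, {self.end}) "
                f"for {self.accession}"
            )
        if self.start > self.end:
            raise ValueError(
                f"start > end ({self.start} > {self.end}) for {self.accession}"
            )
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.accession}")


@dataclass(frozen=True)
class DomainAnnotation:
    """All domain hits of one transcript plus localization predictions."""

    transcript_id: str
    hits: tuple[DomainHit, ...]
    has_tm: bool = False
    has_signal: bool = False

    def validate(self) -> None:
        for h in self.hits:
            h.validate()

    def accessions(self, max_evalue: float | None) -> Counter:
        """Multiset of accessions after the e-value filter."""
        if max_evalue is None:
            return Counter(h.accession for h in self.hits)
        return Counter(h.accession for h in self.hits if h.evalue <= max_evalue)


@dataclass(frozen=True)
class Ruleset:
    """Configurable family rules for the receptor screen.

    ``max_evalue`` drops weak hits before any rule is evaluated;
    ``tir_requires_tm`` controls whether a complete TLR-like call needs a
    predicted transmembrane segment (the default) or only TIR + Ig.
    """

    tir: str = TIR
    ig_like: str = IG_LIKE
    nacht: str = NACHT
    lrr: str = LRR
    gps: str = GPS
    ctl: str = CTL
    srcr: frozenset = SRCR_ACCESSIONS
    seven_tm: frozenset = SEVEN_TM_ACCESSIONS
    precedence: tuple = DEFAULT_PRECEDENCE
    max_evalue: float | None = 1e-5
    tir_requires_tm: bool = True

    def with_overrides(self, **kwargs) -> "Ruleset":
        return replace(self, **kwargs)

    def satisfies(self, family: str, acc: Counter, has_tm: bool) -> bool:
        """Whether the accession multiset + tm flag meets one family's rule.

        Rules are evaluated independently of precedence; use
        :func:`classify_receptor` for the resolved single-family call.
        """
        if family == "TLR_like":
            ok = self.tir in acc and acc[self.ig_like] >= 1
            return ok and (has_tm or not self.tir_requires_tm)
        if family == "TIR_only":
            return self.tir in acc and not (
                acc[self.ig_like] >= 1 and (has_tm or not self.tir_requires_tm)
            )
        if family == "NLR_bona_fide":
            return self.nacht in acc and acc[self.lrr] >= 1
        if family == "NACHT_only":
            return self.nacht in acc and acc[self.lrr] == 0
        if family == "GPCR_GPS_7TM":
            return any(a in acc for a in self.seven_tm) and self.gps in acc
        if family == "GPCR_7TM":
            return any(a in acc for a in self.seven_tm)
        if family == "SRCR":
            return any(a in acc for a in self.srcr)
        if family == "CTLD":
            return self.ctl in acc
        raise KeyError(f"unknown receptor family {family!r}")


DEFAULT_RULESET = Ruleset()


@dataclass(frozen=True)
class ReceptorCall:
    transcript_id: str
    family: str  # one of FAMILIES or "none"
    localization: str  # "membrane_bound" | "non_membrane"
    matched_accessions: tuple[str, ...] = ()


def classify_receptor(
    annotation: DomainAnnotation, ruleset: Ruleset = DEFAULT_RULESET
) -> ReceptorCall:
    """Assign a transcript to a single receptor family.

    Every family rule is a predicate over the transcript's filtered accession
    multiset; the first satisfied rule in the ruleset's precedence order wins.
    Accessions not referenced by any rule are ignored. Localization is
    membrane-bound iff a transmembrane segment was predicted.
    """
    annotation.validate()
    acc = annotation.accessions(ruleset.max_evalue)
    family = "none"
    for cand in ruleset.precedence:
        if ruleset.satisfies(cand, acc, annotation.has_tm):
            family = cand
            break
    relevant = (
        {ruleset.tir, ruleset.ig_like, ruleset.nacht, ruleset.lrr,
         ruleset.gps, ruleset.ctl}
        | set(ruleset.srcr)
        | set(ruleset.seven_tm)
    )
    matched = tuple(sorted(a for a in acc if a in relevant))
    localization = "membrane_bound" if annotation.has_tm else "non_membrane"
    return ReceptorCall(annotation.transcript_id, family, localization, matched)


def _annotations_from_table(
    table: pd.DataFrame, flags: pd.DataFrame | None
) -> list[DomainAnnotation]:
    required = {"transcript_id", "accession", "name", "start", "end", "evalue"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"domain table is missing columns: {sorted(missing)}")
    dups = table.duplicated(subset=["transcript_id", "accession", "start"])
    if dups.any():
        warnings.warn(
            f"dropping {int(dups.sum())} duplicate (transcript, accession, "
            "start) domain rows",
            stacklevel=2,
        )
        table = table[~dups]
    flag_map: dict[str, tuple[bool, bool]] = {}
    if flags is not None:
        for row in flags.itertuples(index=False):
            flag_map[str(row.transcript_id)] = (
                bool(row.has_tm),
                bool(getattr(row, "has_signal", False)),
            )
    out = []
    transcripts = sorted(
        set(table["transcript_id"].astype(str)) | set(flag_map)
    )
    grouped = {
        str(tid): grp for tid, grp in table.groupby("transcript_id", sort=False)
    }
    for tid in transcripts:
        grp = grouped.get(tid)
        hits: tuple[DomainHit, ...] = ()
        if grp is not None:
            grp = grp.sort_values(["start", "end", "accession"])
            hits = tuple(
                DomainHit(
                    str(r.accession), str(r.name), int(r.start), int(r.end),
                    float(r.evalue),
                )
                for r in grp.itertuples(index=False)
            )
        has_tm, has_signal = flag_map.get(tid, (False, False))
        out.append(DomainAnnotation(tid, hits, has_tm, has_signal))
    return out


def screen_transcriptome(
    table: pd.DataFrame,
    flags: pd.DataFrame | None = None,
    ruleset: Ruleset = DEFAULT_RULESET,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Screen a whole annotation table for receptor families.

    Parameters
    ----------
    table
        Long-format domain table with columns transcript_id, accession, name,
        start, end, evalue (one row per domain hit).
    flags
        Optional per-transcript table with has_tm / has_signal booleans.
        Transcripts present only in ``flags`` are classified on an empty
        hit list.

    Returns
    -------
    tally, calls
        ``tally`` counts transcripts per family (families with zero hits and
        the "none" class excluded); ``calls`` is one row per transcript.
        Both are invariant to the row order of the input.
    """
    annotations = _annotations_from_table(table, flags)
    calls = [classify_receptor(a, ruleset) for a in annotations]
    tally = Counter(c.family for c in calls if c.family != "none")
    call_df = pd.DataFrame(
        {
            "transcript_id": [c.transcript_id for c in calls],
            "family": [c.family for c in calls],
            "localization": [c.localization for c in calls],
            "matched_accessions": [
                ",".join(c.matched_accessions) for c in calls
            ],
        }
    )
    return dict(sorted(tally.items())), call_df


def read_domain_table(path) -> pd.DataFrame:
    """Read the 6-column tab-separated domain-hit dialect."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    return df


def read_flags_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    for col in ("has_tm", "has_signal"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def read_domtblout(path) -> pd.DataFrame:
    """Parse HMMER hmmscan --domtblout into the 6-column domain-table dialect.

    Assumes hmmscan orientation (target = Pfam model, query = transcript),
    the convention of Trinotate-style annotation runs. Uses the per-domain
    alignment coordinates (ali_from/ali_to) and the per-domain independent
    e-value. Comment lines start with '#'; the free-text description at the
    end of each row may contain spaces.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 22:
                raise ValueError(f"malformed domtblout row: {line!r}")
            rows.append(
                {
                    "transcript_id": parts[3],
                    "accession": parts[1].split(".")[0],
                    "name": parts[0],
                    "start": int(parts[17]),
                    "end": int(parts[18]),
                    "evalue": float(parts[12]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "accession", "name", "start", "end", "evalue"],
    )
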