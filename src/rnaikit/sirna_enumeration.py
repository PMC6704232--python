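"""Enumeration of candidate siRNA duplexes and transcriptome matching.

A long dsRNA trigger is split into every k-mer window (k defaults to 21, the
canonical Dicer product length).  Each window defines an siRNA duplex: the
*sense* strand equals the trigger window (same polarity as the target mRNA)
and the *antisense* strand — the candidate guide — is its reverse complement.

Matching against a transcript database is exact-by-construction: a hash
index over transcript k-mers answers perfect-match queries, and a
pigeonhole seed-and-verify scheme extends this to 1-2 mismatches.  Both the
sense and the antisense k-mer of every duplex are searched, since a dsRNA
trigger produces siRNAs of both polarities and constructs may be cloned in
either orientation.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .sequence_io import (
    RNA_BASES,
    NucleotideSequence,
    TranscriptDatabase,
    reverse_complement,
)

logger = logging.getLogger(__name__)

#: Allowed siRNA duplex lengths (Dicer products are 19-25 bp).
K_BOUNDS = (19, 25)

SENSE_MATCH = "sense-match"
ANTISENSE_MATCH = "antisense-match"


@dataclass(frozen=True)
class SiRNADuplex:
    """One k-mer window of a trigger with both duplex strands.

    ``start`` is the 0-based offset of the half-open window
    ``[start, start + k)`` on the trigger; ``antisense`` is the reverse
    complement of ``sense`` and is the candidate guide strand.
    """

    trigger_id: str
    start: int
    k: int
    sense: str
    antisense: str

    def __post_init__(self) -> None:
        if len(self.sense) != self.k or len(self.antisense) != self.k:
            raise ValueError("duplex strands must have length k")

    @property
    def end(self) -> int:
        """Exclusive end of the window on the trigger."""
        return self.start + self.k


@dataclass(frozen=True)
class TargetHit:
    """Placement of one siRNA strand on one transcript.

    ``position`` is the 0-based start of the aligned window on the
    transcript.  ``orientation`` records which strand of the duplex matched
    the transcript: a *sense-match* means the antisense (guide) strand can
    base-pair with the transcript, which is the silencing-relevant case.
    """

    sirna: SiRNADuplex
    transcript_id: str
    position: int
    orientation: str
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.orientation not in (SENSE_MATCH, ANTISENSE_MATCH):
            raise ValueError(f"invalid orientation {self.orientation!r}")
        if self.mismatches < 0:
            raise ValueError("mismatch count must be >= 0")


def enumerate_sirnas(
    trigger: NucleotideSequence,
    k: int = 21,
    k_bounds: tuple[int, int] = K_BOUNDS,
) -> list[SiRNADuplex]:
    """Split a trigger into all k-mer siRNA duplexes, ordered by start.

    Windows containing a non-ACGU symbol have no defined pairing energy and
    are skipped (the number skipped is logged).  A trigger shorter than
    ``k`` yields an empty list.
    """
    lo, hi = k_bounds
    if not lo <= k <= hi:
        raise ValueError(f"siRNA length k={k} outside allowed range [{lo}, {hi}]")
    seq = trigger.residues
    duplexes: list[SiRNADuplex] = []
    skipped = 0
    # Track the most recent ambiguous position to skip windows in O(1).
    last_bad = -1
    for i, base in enumerate(seq):
        if base not in RNA_BASES:
            last_bad = i
        start = i - k + 1
        if start < 0:
            continue
        if last_bad >= start:
            skipped += 1
            continue
        sense = seq[start : start + k]
        duplexes.append(
            SiRNADuplex(
                trigger_id=trigger.identifier,
                start=start,
                k=k,
                sense=sense,
                antisense=reverse_complement(sense),
            )
        )
    if skipped:
        logger.info(
            "trigger %s: skipped %d windows containing ambiguous symbols",
            trigger.identifier,
            skipped,
        )
    return duplexes


class KmerMatcher:
    """Mismatch-tolerant k-mer search over a transcript database.

    For ``max_mismatches == 0`` a plain hash index of all transcript k-mers
    is queried.  For 1-2 mismatches the query is partitioned into
    ``max_mismatches + 1`` segments; by pigeonhole at least one segment of
    any hit matches exactly, so exact segment lookups generate candidates
    that are then verified by Hamming distance.
    """

    def __init__(self, db: TranscriptDatabase, k: int, max_mismatches: int = 0):
        if len(db) == 0:
            raise ValueError("transcript database is empty")
        if max_mismatches not in (0, 1, 2):
            raise ValueError("max_mismatches must be 0, 1 or 2")
        self.db = db
        self.k = k
        self.max_mismatches = max_mismatches
        self._segments = self._segment_bounds(k, max_mismatches + 1)
        # index[(segment_index, segment_string)] -> [(transcript_id, window_start)]
        self._index: dict[tuple[int, str], list[tuple[str, int]]] = defaultdict(list)
        for entry in db:
            seq = entry.residues
            for pos in range(len(seq) - k + 1):
                window = seq[pos : pos + k]
                for si, (a, b) in enumerate(self._segments):
                    self._index[(si, window[a:b])].append((entry.identifier, pos))

    @staticmethod
    def _segment_bounds(k: int, n_segments: int) -> list[tuple[int, int]]:
        base, extra = divmod(k, n_segments)
        bounds = []
        a = 0
        for i in range(n_segments):
            b = a + base + (1 if i < extra else 0)
            bounds.append((a, b))
            a = b
        return bounds

    def query(self, kmer: str) -> list[tuple[str, int, int]]:
        """All placements of ``kmer`` with at most ``max_mismatches``.

        Returns ``(transcript_id, position, mismatches)`` triples,
        duplicate-free.
        """
        if len(kmer) != self.k:
            raise ValueError("query length differs from index k")
        seen: dict[tuple[str, int], int] = {}
        for si, (a, b) in enumerate(self._segments):
            for tid, pos in self._index.get((si, kmer[a:b]), ()):
                key = (tid, pos)
                if key in seen:
                    continue
                window = self.db[tid].residues[pos : pos + self.k]
                mm = sum(x != y for x, y in zip(kmer, window))
                if mm <= self.max_mismatches:
                    seen[key] = mm
        return [(tid, pos, mm) for (tid, pos), mm in seen.items()]


def find_hits(
    duplexes: list[SiRNADuplex],
    db: TranscriptDatabase,
    max_mismatches: int = 0,
) -> list[TargetHit]:
    """Locate every placement of every duplex strand on the database.

    Both orientations are searched; results are complete (equivalent to a
    sliding-window Hamming scan), duplicate-free, and deterministically
    ordered by (duplex start, transcript order, position, orientation).
    """
    if len(db) == 0:
        raise ValueError("transcript database is empty")
    if not duplexes:
        return []
    k = duplexes[0].k
    matcher = KmerMatcher(db, k, max_mismatches)
    order = {tid: i for i, tid in enumerate(db.identifiers)}
    hits: list[TargetHit] = []
    for duplex in duplexes:
        for strand, orientation in (
            (duplex.sense, SENSE_MATCH),
            (duplex.antisense, ANTISENSE_MATCH),
        ):
            for tid, pos, mm in matcher.query(strand):
                hits.append(TargetHit(duplex, tid, pos, orientation, mm))
    hits.sort(
        key=lambda h: (
            h.sirna.start,
            order[h.transcript_id],
            h.position,
            h.orientation,
        )
    )
    logger.info(
        "%d duplexes -> %d hits (max_mismatches=%d)",
        len(duplexes),
        len(hits),
        max_mismatches,
    )
    return hits


def hits_per_transcript(hits: list[TargetHit]) -> pd.Series:
    """Hit counts grouped by transcript, descending, ties by identifier."""
    counts: dict[str, int] = defaultdict(int)
    for hit in hits:
        counts[hit.transcript_id] += 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.Series(
        [c for _, c in ordered],
        index=pd.Index([t for t, _ in ordered], name="transcript_id"),
        name="hits",
        dtype=int,
    )


def hits_to_table(hits: list[TargetHit]) -> pd.DataFrame:
    """Hit list as a user-facing table with 1-based coordinates."""
    rows = [
        {
            "trigger_id": h.sirna.trigger_id,
            "sirna_start": h.sirna.start + 1,
            "sense_sequence": h.sirna.sense,
            "transcript_id": h.transcript_id,
            "position": h.position + 1,
            "orientation": h.orientation,
            "mismatches": h.mismatches,
        }
        for h in hits
    ]
    columns = [
        "trigger_id",
        "sirna_start",
        "sense_sequence",
        "transcript_id",
        "position",
        "orientation",
        "mismatches",
    ]
    return pd.DataFrame(rows, columns=columns)
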