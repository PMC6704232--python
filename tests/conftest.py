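"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the library's own algorithms: hit finding is
checked against a naive sliding-window Hamming scan, and the windowed
partition function against exhaustive enumeration of all secondary
structures under the same reduced energy model.
"""

from __future__ import annotations

from functools import lru_cache
from math import exp

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rnaikit import (
    NucleotideSequence,
    TranscriptDatabase,
    default_model,
)
from rnaikit.accessibility import PAIRS, AccessibilityParams, FoldEnergyModel
from rnaikit.sirna_enumeration import ANTISENSE_MATCH, SENSE_MATCH

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def nn_model():
    return default_model()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_seq(identifier: str, residues: str) -> NucleotideSequence:
    return NucleotideSequence(identifier, residues)


def make_db(*seqs: NucleotideSequence) -> TranscriptDatabase:
    return TranscriptDatabase(list(seqs))


# ---------------------------------------------------------------------------
# Oracle 1: naive Hamming scan for hit finding.
# ---------------------------------------------------------------------------

def brute_force_hits(duplexes, db, max_mismatches):
    """Every placement of every duplex strand by direct Hamming scan.

    Returns a set of (sirna_start, transcript_id, position, orientation,
    mismatches) tuples for comparison with ``find_hits``.
    """
    found = set()
    for duplex in duplexes:
        for strand, orientation in (
            (duplex.sense, SENSE_MATCH),
            (duplex.antisense, ANTISENSE_MATCH),
        ):
            for entry in db:
                seq = entry.residues
                for pos in range(len(seq) - duplex.k + 1):
                    window = seq[pos : pos + duplex.k]
                    mm = sum(a != b for a, b in zip(strand, window))
                    if mm <= max_mismatches:
                        found.add(
                            (duplex.start, entry.identifier, pos, orientation, mm)
                        )
    return found


def brute_force_hits_vectorized(duplexes, db, max_mismatches):
    """Same oracle as :func:`brute_force_hits`, vectorized for larger
    databases: mismatch counts from a sliding-window comparison matrix."""
    base_codes = {b: i for i, b in enumerate("ACGU")}
    found = set()
    encoded_db = {
        e.identifier: np.array([base_codes.get(b, 4) for b in e.residues])
        for e in db
    }
    for duplex in duplexes:
        for strand, orientation in (
            (duplex.sense, SENSE_MATCH),
            (duplex.antisense, ANTISENSE_MATCH),
        ):
            query = np.array([base_codes[b] for b in strand])
            for tid, enc in encoded_db.items():
                if len(enc) < duplex.k:
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(enc, duplex.k)
                mismatches = (windows != query).sum(axis=1)
                for pos in np.nonzero(mismatches <= max_mismatches)[0]:
                    found.add(
                        (duplex.start, tid, int(pos), orientation, int(mismatches[pos]))
                    )
    return found


# ---------------------------------------------------------------------------
# Oracle 2: exhaustive secondary-structure enumeration for accessibility.
# ---------------------------------------------------------------------------

_PAIRABLE = frozenset(PAIRS)


def enumerate_structures(seq: str, span: int, min_hairpin: int = 3):
    """All secondary structures of ``seq`` as frozensets of (i, j) pairs.

    Pairs must be Watson-Crick or GU, enclose at least ``min_hairpin``
    unpaired nucleotides and span at most ``span`` nucleotides.
    """

    n = len(seq)

    @lru_cache(maxsize=None)
    def structs(i: int, j: int) -> tuple[frozenset, ...]:
        if i >= j:
            return (frozenset(),)
        out = list(structs(i, j - 1))  # j unpaired
        for k in range(max(i, j - span), j - min_hairpin):
            if (seq[k], seq[j]) in _PAIRABLE:
                for left in structs(i, k - 1):
                    for inner in structs(k + 1, j - 1):
                        out.append(left | inner | {(k, j)})
        return tuple(out)

    return structs(0, n - 1)


def structure_energy(seq: str, pairs: frozenset, model: FoldEnergyModel) -> float:
    """Reduced-model energy: stack terms for directly stacked pairs, one
    constant loop penalty for every other pair."""
    energy = 0.0
    for (i, j) in pairs:
        if (i + 1, j - 1) in pairs:
            energy += model.nn.stack(seq[i] + seq[i + 1], seq[j] + seq[j - 1])
        else:
            energy += model.loop_penalty
    return energy


def oracle_unpaired_probability(
    seq: str,
    stretch_start: int,
    u: int,
    params: AccessibilityParams,
    model: FoldEnergyModel,
) -> float:
    """Boltzmann probability that ``[stretch_start, stretch_start+u)`` is
    entirely unpaired, by exhaustive enumeration (single window)."""
    rt = model.nn.rt
    structures = enumerate_structures(
        seq, params.span_L, model.hairpin_min_unpaired
    )
    lo, hi = stretch_start, stretch_start + u - 1
    z = 0.0
    z_free = 0.0
    for pairs in structures:
        weight = exp(-structure_energy(seq, pairs, model) / rt)
        z += weight
        if all(not (lo <= i <= hi or lo <= j <= hi) for i, j in pairs):
            z_free += weight
    return z_free / z


def oracle_partition_function(seq: str, params: AccessibilityParams, model: FoldEnergyModel) -> float:
    rt = model.nn.rt
    structures = enumerate_structures(seq, params.span_L, model.hairpin_min_unpaired)
    return sum(exp(-structure_energy(seq, pairs, model) / rt) for pairs in structures)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
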