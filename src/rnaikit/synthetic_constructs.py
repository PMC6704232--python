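"""Synthetic validation constructs and evaluation statistics.

Two families of synthetic triggers make every pipeline stage testable
without any external sequence download:

* *molecular-clock* constructs — copies of a base sequence with ``p`` percent
  of positions re-drawn uniformly at random (the replacement may equal the
  original, so expected identity is ``100 - 0.75 p`` percent), emulating
  neutral sequence divergence at ~2% per million years;
* *window* constructs — a single block copied from the base sequence at its
  original coordinates, embedded in a fully randomized backbone, so the
  trigger matches the target only inside the window.

The module also carries the small published benchmark table (per-construct
hit counts and mean silencing index for a barley Mlo construct series) and
the correlation harness used to evaluate predictions against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_io import NucleotideSequence, write_fasta

_BASES = np.array(list("ACGU"))

#: Name/percent pairs of the standard clock series: names count simulated
#: millions of years, divergence accrues at 2% per million years.
CLOCK_SERIES: tuple[tuple[str, float], ...] = tuple(
    (f"{my}MY", 2.0 * my) for my in (0, 1, 2, 3, 4, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50)
)


@dataclass(frozen=True)
class ClockConstruct:
    """A percent-randomized copy of a base sequence."""

    name: str
    percent_randomized: float
    sequence: NucleotideSequence
    altered_positions: frozenset[int]
    seed: int


def random_sequence(
    length: int, rng: np.random.Generator, identifier: str = "random"
) -> NucleotideSequence:
    """Uniform random RNA sequence of the given length."""
    residues = "".join(rng.choice(_BASES, size=length))
    return NucleotideSequence(identifier, residues)


def generate_clock_construct(
    base: NucleotideSequence,
    percent: float,
    rng_seed: int,
    name: str | None = None,
) -> ClockConstruct:
    """Randomize ``round(percent * len / 100)`` distinct positions of ``base``.

    Positions are drawn uniformly without replacement; each receives a base
    drawn uniformly from {A,C,G,U}, the original included, so on average a
    quarter of altered positions keep their identity.  Fully reproducible
    from ``rng_seed``.
    """
    if not 0 <= percent <= 100:
        raise ValueError(f"percent must lie in [0, 100], got {percent}")
    rng = np.random.default_rng(rng_seed)
    n = len(base)
    n_alter = round(percent * n / 100)
    positions = rng.choice(n, size=n_alter, replace=False) if n_alter else np.array([], dtype=int)
    residues = list(base.residues)
    new_bases = rng.choice(_BASES, size=n_alter)
    for pos, b in zip(positions, new_bases):
        residues[pos] = b
    if name is None:
        name = f"{base.identifier}_p{percent:g}"
    return ClockConstruct(
        name=name,
        percent_randomized=percent,
        sequence=NucleotideSequence(name, "".join(residues)),
        altered_positions=frozenset(int(p) for p in positions),
        seed=rng_seed,
    )


def generate_window_construct(
    base: NucleotideSequence,
    window_start: int,
    window_len: int,
    backbone: NucleotideSequence,
    name: str | None = None,
) -> NucleotideSequence:
    """Backbone with ``[window_start, window_start + window_len)`` replaced
    by the base sequence's same-coordinate fragment."""
    if len(base) != len(backbone):
        raise ValueError(
            f"base length {len(base)} != backbone length {len(backbone)}"
        )
    if window_start < 0 or window_start + window_len > len(base):
        raise ValueError("window outside sequence bounds")
    residues = (
        backbone.residues[:window_start]
        + base.residues[window_start : window_start + window_len]
        + backbone.residues[window_start + window_len :]
    )
    if name is None:
        name = f"{window_start + 1}-{window_start + window_len}W"
    return NucleotideSequence(name, residues)


def percent_identity(a: NucleotideSequence, b: NucleotideSequence) -> float:
    """Ungapped positional identity, in percent (equal lengths required)."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    matches = sum(x == y for x, y in zip(a.residues, b.residues))
    return 100.0 * matches / len(a)


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient.

    Requires two equal-length vectors of at least three points, neither
    constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def load_benchmark_table() -> pd.DataFrame:
    """The packaged construct benchmark: counts per mode plus mean_si."""
    with resources.as_file(
        resources.files("rnaikit.data").joinpath("mlo_construct_benchmark.tsv")
    ) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def correlation_table(counts: pd.DataFrame, si_column: str = "mean_si") -> dict[str, float]:
    """Pearson correlation of every count column against the silencing index.

    ``counts`` must hold numeric count columns plus ``si_column``; the
    construct name column, if present, is ignored.
    """
    numeric = counts.select_dtypes("number")
    if si_column not in numeric:
        raise ValueError(f"column {si_column!r} missing or non-numeric")
    si = numeric[si_column]
    return {
        col: pearson_r(numeric[col], si)
        for col in numeric.columns
        if col != si_column
    }


def make_fixture_series(
    out_dir: str | Path,
    seed: int,
    base: NucleotideSequence | None = None,
    length: int = 500,
    window_len: int = 100,
) -> pd.DataFrame:
    """Emit the full clock + window construct series as FASTA plus manifest.

    When no base sequence is given, a random one of ``length`` nt is drawn
    from the seed.  The window constructs share one fully randomized
    backbone (the clock construct at 100% randomization), mirroring how the
    experimental series was built.  Returns the manifest table; writes
    ``base.fasta``, ``clock_series.fasta``, ``window_series.fasta`` and
    ``manifest.tsv`` into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if base is None:
        base = random_sequence(length, rng, identifier="target")

    seed_seq = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(len(CLOCK_SERIES))]

    rows = []
    clock_seqs = []
    backbone = None
    for (cname, percent), cseed in zip(CLOCK_SERIES, child_seeds):
        construct = generate_clock_construct(base, percent, cseed, name=cname)
        clock_seqs.append(construct.sequence)
        if percent == 100:
            backbone = construct.sequence
        rows.append(
            {
                "name": cname,
                "series": "clock",
                "percent_randomized": percent,
                "identity_to_base": round(percent_identity(construct.sequence, base), 1),
                "n_altered": len(construct.altered_positions),
            }
        )
    assert backbone is not None, "clock series must include 100% randomization"

    window_seqs = []
    for start in range(0, len(base) - window_len + 1, window_len):
        wseq = generate_window_construct(base, start, window_len, backbone)
        window_seqs.append(wseq)
        rows.append(
            {
                "name": wseq.identifier,
                "series": "window",
                "percent_randomized": np.nan,
                "identity_to_base": round(percent_identity(wseq, base), 1),
                "n_altered": len(base) - window_len,
            }
        )

    write_fasta([base], out / "base.fasta")
    write_fasta(clock_seqs, out / "clock_series.fasta")
    write_fasta(window_seqs, out / "window_series.fasta")
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False, float_format="%.1f")
    return manifest
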