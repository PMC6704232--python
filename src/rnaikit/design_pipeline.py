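"""Workflow orchestration: off-target search and RNAi design modes.

The off-target mode enumerates all siRNAs of a trigger, matches them against
the transcript database and ranks every matched transcript by its number of
HS-classified hits — accessibility is never computed here, since the HS rule
does not use it.  The design mode additionally folds the declared main
target(s), classifies every sense-match hit under the HE rule, paints each
trigger position green or red depending on whether any siRNA covering it
also hits a transcript outside the main-target set, and recommends the
region (default 100 nt) with the most HE hits among those free of red
positions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .accessibility import (
    AccessibilityParams,
    AccessibilityProfile,
    FoldEnergyModel,
    partition_unpaired,
)
from .duplex_thermo import NearestNeighborModel, default_model, strand_selection
from .selection_modes import classify_he, classify_hs
from .sequence_io import NucleotideSequence, TranscriptDatabase
from .sirna_enumeration import (
    SENSE_MATCH,
    TargetHit,
    enumerate_sirnas,
    find_hits,
    hits_to_table,
)

logger = logging.getLogger(__name__)

MODE_OFFTARGET = "offtarget"
MODE_DESIGN = "design"

ZONE_GREEN = "green"
ZONE_RED = "red"

_HIT_COLUMNS = [
    "trigger_id",
    "sirna_start",
    "sense_sequence",
    "transcript_id",
    "position",
    "orientation",
    "mismatches",
    "hs_pass",
    "he_pass",
    "delta_mfe",
    "site_lap",
    "failed_rules",
]


@dataclass(frozen=True)
class RunParams:
    """All tunables of a pipeline run."""

    k: int = 21
    max_mismatches: int = 0
    n_terminal: int = 3
    dmfe_threshold: float = 1.0
    accessibility: AccessibilityParams = field(default_factory=AccessibilityParams)
    loop_penalty: float = 5.0
    region_length: int = 100
    require_opposite_end: bool = False

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "max_mismatches": self.max_mismatches,
            "n_terminal": self.n_terminal,
            "dmfe_threshold": self.dmfe_threshold,
            "u": self.accessibility.u,
            "span_L": self.accessibility.span_L,
            "window_W": self.accessibility.window_W,
            "lap_threshold": self.accessibility.threshold,
            "loop_penalty": self.loop_penalty,
            "region_length": self.region_length,
            "require_opposite_end": self.require_opposite_end,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunParams":
        return cls(
            k=int(d.get("k", 21)),
            max_mismatches=int(d.get("max_mismatches", 0)),
            n_terminal=int(d.get("n_terminal", 3)),
            dmfe_threshold=float(d.get("dmfe_threshold", 1.0)),
            accessibility=AccessibilityParams(
                u=int(d.get("u", 8)),
                span_L=int(d.get("span_L", 40)),
                window_W=int(d.get("window_W", 80)),
                threshold=float(d.get("lap_threshold", 0.1)),
            ),
            loop_penalty=float(d.get("loop_penalty", 5.0)),
            region_length=int(d.get("region_length", 100)),
            require_opposite_end=bool(d.get("require_opposite_end", False)),
        )


@dataclass(eq=False)
class DesignReport:
    """Result of one pipeline run.

    ``positions`` has one row per trigger position (1-based) with covering
    total/HS/HE hit counts and the green/red zone call; ``per_transcript``
    summarizes counts per matched transcript; ``hits`` is the full annotated
    hit table; ``recommended_region`` (design mode) is a dict with 1-based
    inclusive ``start``/``end`` and the ``he_count`` achieved, or None.
    """

    trigger_id: str
    mode: str
    params: RunParams
    positions: pd.DataFrame
    per_transcript: pd.DataFrame
    hits: pd.DataFrame
    main_target_ids: tuple[str, ...] = ()
    recommended_region: dict | None = None
    warnings: tuple[str, ...] = ()
    profiles: dict[str, AccessibilityProfile] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DesignReport):
            return NotImplemented
        return (
            self.trigger_id == other.trigger_id
            and self.mode == other.mode
            and self.params == other.params
            and self.main_target_ids == other.main_target_ids
            and self.recommended_region == other.recommended_region
            and self.warnings == other.warnings
            and self.positions.equals(other.positions)
            and self.per_transcript.equals(other.per_transcript)
            and self.hits.equals(other.hits)
        )

    def to_dict(self) -> dict:
        def records(df: pd.DataFrame) -> list[dict]:
            out = []
            for rec in df.to_dict(orient="records"):
                out.append(
                    {
                        k: (None if isinstance(v, float) and np.isnan(v) else v)
                        for k, v in rec.items()
                    }
                )
            return out

        return {
            "trigger_id": self.trigger_id,
            "mode": self.mode,
            "params": self.params.to_dict(),
            "main_target_ids": list(self.main_target_ids),
            "recommended_region": self.recommended_region,
            "warnings": list(self.warnings),
            "positions": records(self.positions),
            "per_transcript": records(self.per_transcript),
            "hits": records(self.hits),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignReport":
        positions = pd.DataFrame(
            d["positions"],
            columns=["position", "total_hits", "hs_hits", "he_hits", "zone"],
        ).astype(
            {
                "position": int,
                "total_hits": int,
                "hs_hits": int,
                "he_hits": int,
                "zone": str,
            }
        )
        per_transcript = pd.DataFrame(
            d["per_transcript"],
            columns=[
                "transcript_id",
                "total_hits",
                "hs_hits",
                "he_hits",
                "is_main_target",
            ],
        ).astype(
            {
                "transcript_id": str,
                "total_hits": int,
                "hs_hits": int,
                "he_hits": int,
                "is_main_target": bool,
            }
        )
        hits = pd.DataFrame(d["hits"], columns=_HIT_COLUMNS)
        hits = _coerce_hit_dtypes(hits)
        return cls(
            trigger_id=d["trigger_id"],
            mode=d["mode"],
            params=RunParams.from_dict(d["params"]),
            positions=positions,
            per_transcript=per_transcript,
            hits=hits,
            main_target_ids=tuple(d["main_target_ids"]),
            recommended_region=d["recommended_region"],
            warnings=tuple(d["warnings"]),
        )


def _coerce_hit_dtypes(hits: pd.DataFrame) -> pd.DataFrame:
    hits = hits.astype(
        {
            "trigger_id": str,
            "sirna_start": int,
            "sense_sequence": str,
            "transcript_id": str,
            "position": int,
            "orientation": str,
            "mismatches": int,
            "hs_pass": bool,
            "he_pass": bool,
            "delta_mfe": float,
            "failed_rules": str,
        }
    )
    hits["site_lap"] = hits["site_lap"].astype(float)
    return hits


def _empty_report(
    trigger: NucleotideSequence,
    mode: str,
    params: RunParams,
    main_target_ids: tuple[str, ...],
    warning: str,
) -> DesignReport:
    logger.warning(warning)
    positions = pd.DataFrame(
        {
            "position": np.arange(1, len(trigger) + 1),
            "total_hits": 0,
            "hs_hits": 0,
            "he_hits": 0,
            "zone": ZONE_GREEN,
        }
    )
    per_transcript = pd.DataFrame(
        columns=["transcript_id", "total_hits", "hs_hits", "he_hits", "is_main_target"]
    ).astype(
        {
            "transcript_id": str,
            "total_hits": int,
            "hs_hits": int,
            "he_hits": int,
            "is_main_target": bool,
        }
    )
    hits = pd.DataFrame(columns=_HIT_COLUMNS)
    hits = _coerce_hit_dtypes(hits)
    return DesignReport(
        trigger_id=trigger.identifier,
        mode=mode,
        params=params,
        positions=positions,
        per_transcript=per_transcript,
        hits=hits,
        main_target_ids=main_target_ids,
        warnings=(warning,),
    )


def _run(
    trigger: NucleotideSequence,
    db: TranscriptDatabase,
    params: RunParams,
    mode: str,
    main_target_ids: tuple[str, ...],
    model: NearestNeighborModel,
) -> DesignReport:
    if len(trigger) < params.k:
        return _empty_report(
            trigger,
            mode,
            params,
            main_target_ids,
            f"trigger {trigger.identifier!r} shorter than siRNA length "
            f"k={params.k}; empty report",
        )

    duplexes = enumerate_sirnas(trigger, params.k)
    hits = find_hits(duplexes, db, params.max_mismatches) if duplexes else []
    logger.info(
        "mode=%s trigger=%s: %d duplexes, %d hits",
        mode,
        trigger.identifier,
        len(duplexes),
        len(hits),
    )

    verdicts = {
        d.start: strand_selection(d, model, params.n_terminal, params.dmfe_threshold)
        for d in duplexes
    }
    hs_by_start = {d.start: classify_hs(d, verdicts[d.start]) for d in duplexes}

    profiles: dict[str, AccessibilityProfile] = {}
    if mode == MODE_DESIGN:
        fold_model = FoldEnergyModel(nn=model, loop_penalty=params.loop_penalty)
        for tid in main_target_ids:
            profiles[tid] = partition_unpaired(
                db[tid], params.accessibility, fold_model
            )
        logger.info("computed accessibility profiles for %d main targets", len(profiles))

    # Per-hit annotation.
    annotated = hits_to_table(hits)
    hs_flags, he_flags, dmfes, laps, failed = [], [], [], [], []
    he_hits: list[TargetHit] = []
    for hit in hits:
        verdict = verdicts[hit.sirna.start]
        hs = hs_by_start[hit.sirna.start]
        dmfes.append(verdict.delta_mfe)
        hs_flags.append(hs)
        if mode == MODE_DESIGN and hit.transcript_id in profiles:
            ev = classify_he(
                hit.sirna,
                verdict,
                hit,
                profiles[hit.transcript_id],
                params.accessibility,
                params.require_opposite_end,
            )
            he_flags.append(ev.he_pass)
            laps.append(
                np.nan
                if ev.accessibility_value is None
                else ev.accessibility_value
            )
            failed.append(";".join(ev.reasons))
            if ev.he_pass:
                he_hits.append(hit)
        else:
            he_flags.append(False)
            laps.append(np.nan)
            failed.append("")
    annotated["hs_pass"] = pd.Series(hs_flags, dtype=bool)
    annotated["he_pass"] = pd.Series(he_flags, dtype=bool)
    annotated["delta_mfe"] = pd.Series(dmfes, dtype=float)
    annotated["site_lap"] = pd.Series(laps, dtype=float)
    annotated["failed_rules"] = pd.Series(failed, dtype=str)
    annotated = _coerce_hit_dtypes(annotated)

    # Per-position coverage counts and zoning.
    n = len(trigger)
    total_cov = np.zeros(n, dtype=int)
    hs_cov = np.zeros(n, dtype=int)
    he_cov = np.zeros(n, dtype=int)
    red = np.zeros(n, dtype=bool)
    main_set = set(main_target_ids)
    for i, hit in enumerate(hits):
        a, b = hit.sirna.start, hit.sirna.end
        total_cov[a:b] += 1
        if hs_flags[i]:
            hs_cov[a:b] += 1
            if mode == MODE_DESIGN and hit.transcript_id not in main_set:
                red[a:b] = True
        if he_flags[i]:
            he_cov[a:b] += 1
    positions = pd.DataFrame(
        {
            "position": np.arange(1, n + 1),
            "total_hits": total_cov,
            "hs_hits": hs_cov,
            "he_hits": he_cov,
            "zone": np.where(red, ZONE_RED, ZONE_GREEN),
        }
    )

    # Per-transcript summary, ranked by HS count then total then identifier.
    rows = []
    for tid in db.identifiers:
        mask = annotated["transcript_id"] == tid
        total = int(mask.sum())
        if total == 0:
            continue
        rows.append(
            {
                "transcript_id": tid,
                "total_hits": total,
                "hs_hits": int(annotated.loc[mask, "hs_pass"].sum()),
                "he_hits": int(annotated.loc[mask, "he_pass"].sum()),
                "is_main_target": tid in main_set,
            }
        )
    rows.sort(key=lambda r: (-r["hs_hits"], -r["total_hits"], r["transcript_id"]))
    per_transcript = pd.DataFrame(
        rows,
        columns=["transcript_id", "total_hits", "hs_hits", "he_hits", "is_main_target"],
    )
    if per_transcript.empty:
        per_transcript = per_transcript.astype(
            {
                "transcript_id": str,
                "total_hits": int,
                "hs_hits": int,
                "he_hits": int,
                "is_main_target": bool,
            }
        )

    recommended = None
    if mode == MODE_DESIGN:
        recommended = _recommend_region(
            n, params.region_length, params.k, he_hits, red
        )

    return DesignReport(
        trigger_id=trigger.identifier,
        mode=mode,
        params=params,
        positions=positions,
        per_transcript=per_transcript,
        hits=annotated,
        main_target_ids=main_target_ids,
        recommended_region=recommended,
        profiles=profiles,
    )


def _recommend_region(
    trigger_len: int,
    region_length: int,
    k: int,
    he_hits: list[TargetHit],
    red: np.ndarray,
) -> dict | None:
    """Best design region: maximum HE-hit count among red-free windows.

    A window of ``region_length`` nt (capped at the trigger length) counts
    the HE hits whose siRNA lies fully inside it; windows containing any
    red position are disqualified; ties break toward the 5' end.  Returns
    None when no qualifying window contains an HE hit.
    """
    rlen = min(region_length, trigger_len)
    he_starts = [h.sirna.start for h in he_hits]
    best = None
    for s in range(trigger_len - rlen + 1):
        if red[s : s + rlen].any():
            continue
        count = sum(1 for a in he_starts if s <= a and a + k <= s + rlen)
        if count >= 1 and (best is None or count > best[1]):
            best = (s, count)
    if best is None:
        return None
    s, count = best
    return {"start": s + 1, "end": s + rlen, "he_count": count}


def run_offtarget_mode(
    trigger: NucleotideSequence,
    db: TranscriptDatabase,
    params: RunParams | None = None,
    model: NearestNeighborModel | None = None,
) -> DesignReport:
    """Off-target search: HS classification only, no folding.

    Ranks every matched transcript as a putative (off-)target by its HS
    hit count.
    """
    params = params or RunParams()
    return _run(trigger, db, params, MODE_OFFTARGET, (), model or default_model())


def run_design_mode(
    trigger: NucleotideSequence,
    db: TranscriptDatabase,
    main_target_ids: list[str] | tuple[str, ...],
    params: RunParams | None = None,
    model: NearestNeighborModel | None = None,
) -> DesignReport:
    """RNAi design: HE classification on the declared main target(s).

    ``main_target_ids`` may name several transcripts (e.g. a gene family);
    hits on any of them are intended, hits elsewhere cause red zoning.
    """
    params = params or RunParams()
    for tid in main_target_ids:
        if tid not in db:
            raise KeyError(f"main target {tid!r} not in database")
    if not main_target_ids:
        raise ValueError("design mode requires at least one main target")
    return _run(
        trigger,
        db,
        params,
        MODE_DESIGN,
        tuple(main_target_ids),
        model or default_model(),
    )


def export_report(report: DesignReport, out_dir: str | Path) -> list[Path]:
    """Write hit/position/transcript TSVs, a JSON summary and a plot.

    Outputs are byte-deterministic for identical inputs and parameters
    (fixed column order, fixed float formatting, sorted JSON keys).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def write_tsv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
        written.append(path)

    write_tsv(report.hits, "hits.tsv")
    write_tsv(report.positions, "positions.tsv")
    write_tsv(report.per_transcript, "transcripts.tsv")
    for tid, profile in report.profiles.items():
        write_tsv(profile.to_table(), f"accessibility_{tid}.tsv")

    summary_path = out / "summary.json"
    summary_path.write_text(
        json.dumps(report.to_dict(), sort_keys=True, indent=2) + "\n"
    )
    written.append(summary_path)

    written.append(_plot_report(report, out / "report.png"))
    return written


def _plot_report(report: DesignReport, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    pos = report.positions["position"]
    ax.plot(pos, report.positions["total_hits"], color="tab:blue", label="total hits")
    ax.plot(pos, report.positions["hs_hits"], color="tab:orange", label="HS hits")
    if report.mode == MODE_DESIGN:
        ax.plot(pos, report.positions["he_hits"], color="tab:red", label="HE hits")
    red = (report.positions["zone"] == ZONE_RED).to_numpy()
    if red.any():
        ax.fill_between(
            pos,
            0,
            max(1, int(report.positions["total_hits"].max())),
            where=red,
            color="red",
            alpha=0.15,
            label="off-target zone",
        )
    if report.recommended_region:
        ax.axvspan(
            report.recommended_region["start"],
            report.recommended_region["end"],
            color="green",
            alpha=0.15,
            label="recommended region",
        )
    ax.set_xlabel(f"position on trigger {report.trigger_id}")
    ax.set_ylabel("siRNA hits covering position")
    ax.set_title(f"{report.mode} mode")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
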