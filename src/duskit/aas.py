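"""AlkAnilineSeq scoring: read mapping, 5'-end tallies, stop ratios, D calls.

The score surface is the per-position *stop ratio* — the number of reads
whose 5' end maps at a position divided by the number of reads covering that
position — which ranges from 0 to 1.  Because the cleavage chemistry
deprotects a ligatable 5'-phosphate at the nucleotide *after* the
dihydrouridine (N+1), a D site is reported at (stop position - 1).

Mapping is an exhaustive end-to-end scan: each read is scored at every
offset of every reference by Hamming mismatches, the best placement wins,
and reads with tied best placements are discarded as multimapped so the
pipeline stays deterministic.  This deliberately replaces a production
aligner at desk scale; the fixture generator keeps references mutually
distinguishable so the tie rule rarely triggers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .core import DSiteAnnotation, ReferenceBundle

DEFAULT_MAX_MISMATCH = 2
DEFAULT_MIN_COV = 10
#: Call threshold on the stop ratio; chosen above the ~0.04 ceiling observed
#: in Dus-null libraries so background never produces a call.
DEFAULT_CALL_THRESHOLD = 0.05


@dataclass(frozen=True)
class AlignedRead:
    """A read placed end-to-end on a reference (1-based, closed interval)."""

    read_id: str
    trna_id: str
    start_index: int
    end_index: int
    mismatches: int


@dataclass
class MappingReport:
    total: int = 0
    mapped: int = 0
    unmapped: int = 0
    multimapped: int = 0


def _encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string as bytes; N becomes 0 and matches nothing."""
    s = seq.upper().replace("T", "U").replace("N", "\x00")
    return np.frombuffer(s.encode("latin-1"), dtype=np.uint8)


def map_reads(
    reads,
    bundle: ReferenceBundle,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> tuple[list[AlignedRead], MappingReport]:
    """Place reads on the reference set by exhaustive end-to-end Hamming scan.

    ``reads`` is an iterable of ``(read_id, sequence)`` pairs (T/U unified;
    N counts as a mismatch everywhere).  A read whose best score exceeds
    ``max_mismatch`` is unmapped; a read with two or more best-score
    placements anywhere is discarded as multimapped.  Reads longer than every
    reference are unmapped, not an error.
    """
    encoded_refs = [(ref.id, _encode(ref.sequence)) for ref in bundle.references]
    report = MappingReport()
    aligned: list[AlignedRead] = []

    # identical read sequences share a placement; scan each unique sequence once
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for read_id, seq in reads:
        key = seq.upper().replace("T", "U")
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(read_id)
    placements: dict[str, tuple[str, int, int] | None] = {}
    for seq in order:
        arr = _encode(seq)
        r = len(arr)
        best = None  # (score, trna_id, offset)
        n_best = 0
        for trna_id, ref_arr in encoded_refs:
            if r > len(ref_arr) or r == 0:
                continue
            windows = sliding_window_view(ref_arr, r)
            mismatches = (windows != arr).sum(axis=1)
            local_min = int(mismatches.min())
            if best is None or local_min < best[0]:
                best = (local_min, trna_id, int(np.flatnonzero(mismatches == local_min)[0]))
                n_best = int((mismatches == local_min).sum())
            elif local_min == best[0]:
                n_best += int((mismatches == local_min).sum())
        if best is None or best[0] > max_mismatch:
            placements[seq] = None  # unmapped
        elif n_best > 1:
            placements[seq] = ("", -1, best[0])  # multimapped sentinel
        else:
            placements[seq] = (best[1], best[2], best[0])

    for seq in order:
        placement = placements[seq]
        for read_id in groups[seq]:
            report.total += 1
            if placement is None:
                report.unmapped += 1
            elif placement[1] < 0:
                report.multimapped += 1
            else:
                trna_id, offset, score = placement
                report.mapped += 1
                aligned.append(
                    AlignedRead(
                        read_id=read_id,
                        trna_id=trna_id,
                        start_index=offset + 1,
                        end_index=offset + len(seq),
                        mismatches=score,
                    )
                )
    return aligned, report


@dataclass
class SiteCounts:
    """Per-position 5'-end counts (n5) and read coverage (cov), 1-based."""

    n5: dict[str, np.ndarray]
    cov: dict[str, np.ndarray]

    def get_n5(self, trna_id: str, position: int) -> int:
        return int(self.n5[trna_id][position - 1])

    def get_cov(self, trna_id: str, position: int) -> int:
        return int(self.cov[trna_id][position - 1])


def tally(aligned: list[AlignedRead], bundle: ReferenceBundle) -> SiteCounts:
    """Count read 5' ends and coverage at every reference position.

    Positions without data are present with zeros; per reference,
    sum(cov) equals the summed lengths of the mapped reads.
    """
    n5 = {ref.id: np.zeros(len(ref), dtype=np.int64) for ref in bundle.references}
    cov_diff = {ref.id: np.zeros(len(ref) + 1, dtype=np.int64) for ref in bundle.references}
    for read in aligned:
        n5[read.trna_id][read.start_index - 1] += 1
        cov_diff[read.trna_id][read.start_index - 1] += 1
        cov_diff[read.trna_id][read.end_index] -= 1
    cov = {trna_id: np.cumsum(diff[:-1]) for trna_id, diff in cov_diff.items()}
    return SiteCounts(n5=n5, cov=cov)


@dataclass
class StopProfile:
    """Per-position stop ratios with low-coverage flags (1-based positions)."""

    ratio: dict[str, np.ndarray]
    low_coverage: dict[str, np.ndarray]
    n5: dict[str, np.ndarray] = field(default_factory=dict)
    cov: dict[str, np.ndarray] = field(default_factory=dict)
    min_cov: int = DEFAULT_MIN_COV

    def get_ratio(self, trna_id: str, position: int) -> float:
        return float(self.ratio[trna_id][position - 1])

    def is_flagged(self, trna_id: str, position: int) -> bool:
        return bool(self.low_coverage[trna_id][position - 1])


def stop_ratio(counts: SiteCounts, min_cov: int = DEFAULT_MIN_COV) -> StopProfile:
    """stop_ratio(i) = n5(i) / cov(i) where cov(i) >= min_cov, else 0 + flag."""
    ratio: dict[str, np.ndarray] = {}
    flags: dict[str, np.ndarray] = {}
    for trna_id, n5 in counts.n5.items():
        cov = counts.cov[trna_id]
        low = cov < min_cov
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(low, 0.0, n5 / np.where(cov == 0, 1, cov))
        ratio[trna_id] = r
        flags[trna_id] = low
    return StopProfile(
        ratio=ratio,
        low_coverage=flags,
        n5={k: v.copy() for k, v in counts.n5.items()},
        cov={k: v.copy() for k, v in counts.cov.items()},
        min_cov=min_cov,
    )


@dataclass(frozen=True)
class DSiteCall:
    """A called dihydrouridine site (d_index = stop position - 1)."""

    trna_id: str
    d_index: int
    canonical_label: str | None
    enzyme: str | None
    stop_ratio: float


def infer_d_positions(
    profile: StopProfile,
    bundle: ReferenceBundle,
    threshold: float = DEFAULT_CALL_THRESHOLD,
    mode: str = "annotated",
) -> list[DSiteCall]:
    """Call D sites from a stop profile using the N+1 back-shift.

    In ``annotated`` mode only annotated sites are examined, each read at its
    stop position (site index + 1).  In ``discovery`` mode any position whose
    back-shifted index carries a U and whose ratio reaches the threshold is
    called.
    """
    if mode not in ("annotated", "discovery"):
        raise ValueError(f"unknown mode {mode!r}")
    calls: list[DSiteCall] = []
    if mode == "annotated":
        for ann in bundle.annotations:
            ref = bundle.reference(ann.trna_id)
            stop_pos = ann.seq_index + 1
            if stop_pos > len(ref):
                continue
            r = profile.get_ratio(ann.trna_id, stop_pos)
            if r >= threshold and not profile.is_flagged(ann.trna_id, stop_pos):
                calls.append(
                    DSiteCall(
                        trna_id=ann.trna_id,
                        d_index=ann.seq_index,
                        canonical_label=ann.canonical_label,
                        enzyme=ann.enzyme,
                        stop_ratio=r,
                    )
                )
    else:
        for ref in bundle.references:
            ratios = profile.ratio[ref.id]
            for stop_pos in range(2, len(ref) + 1):
                d_index = stop_pos - 1
                if ref.sequence[d_index - 1] != "U":
                    continue
                r = float(ratios[stop_pos - 1])
                if r >= threshold and not profile.is_flagged(ref.id, stop_pos):
                    ann = bundle.annotation_at(ref.id, d_index)
                    calls.append(
                        DSiteCall(
                            trna_id=ref.id,
                            d_index=d_index,
                            canonical_label=ann.canonical_label if ann else ref.label_for_index(d_index),
                            enzyme=ann.enzyme if ann else None,
                            stop_ratio=r,
                        )
                    )
    return calls


def compare_conditions(
    profile_treated: StopProfile,
    profile_control: StopProfile,
    min_cov: int | None = None,
) -> pd.DataFrame:
    """Per-position percent-of-control table (control stop ratio = 100%).

    percent(i) = 100 x ratio_treated(i) / ratio_control(i).  Positions whose
    control is low-coverage-flagged or zero are reported as undefined (NaN
    percent, status ``undefined_control``), never as infinity.  A flagged
    treated position is marked ``low_coverage_treated``.
    """
    rows = []
    for trna_id, r_ctrl in profile_control.ratio.items():
        if trna_id not in profile_treated.ratio:
            continue
        r_trt = profile_treated.ratio[trna_id]
        for pos in range(1, len(r_ctrl) + 1):
            ctrl = float(r_ctrl[pos - 1])
            trt = float(r_trt[pos - 1])
            ctrl_bad = profile_control.is_flagged(trna_id, pos) or ctrl == 0.0
            trt_flag = profile_treated.is_flagged(trna_id, pos)
            if ctrl_bad:
                percent, status = float("nan"), "undefined_control"
            elif trt_flag:
                percent, status = float("nan"), "low_coverage_treated"
            else:
                percent, status = 100.0 * trt / ctrl, "ok"
            rows.append(
                {
                    "trna_id": trna_id,
                    "position": pos,
                    "d_index": pos - 1,
                    "ratio_treated": trt,
                    "ratio_control": ctrl,
                    "percent_of_control": percent,
                    "status": status,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "trna_id",
            "position",
            "d_index",
            "ratio_treated",
            "ratio_control",
            "percent_of_control",
            "status",
        ],
    )


def enzyme_level_summary(
    comparison: pd.DataFrame, annotations: list[DSiteAnnotation]
) -> pd.DataFrame:
    """Per-enzyme summary of a comparison table restricted to annotated sites.

    For each enzyme: number of defined sites, number decreased (< 100% of
    control), fraction decreased and mean percent-of-control.
    """
    rows = []
    per_enzyme: dict[str, list[float]] = {}
    if len(comparison):
        indexed = comparison.set_index(["trna_id", "position"])
        for ann in annotations:
            key = (ann.trna_id, ann.seq_index + 1)
            if key not in indexed.index:
                continue
            rec = indexed.loc[key]
            if rec["status"] != "ok":
                continue
            per_enzyme.setdefault(ann.enzyme, []).append(float(rec["percent_of_control"]))
    for enzyme in sorted(per_enzyme):
        values = per_enzyme[enzyme]
        n_dec = sum(1 for v in values if v < 100.0)
        rows.append(
            {
                "enzyme": enzyme,
                "n_sites": len(values),
                "n_decreased": n_dec,
                "fraction_decreased": n_dec / len(values),
                "mean_percent_of_control": float(np.mean(values)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "enzyme",
            "n_sites",
            "n_decreased",
            "fraction_decreased",
            "mean_percent_of_control",
        ],
    )


# ---------------------------------------------------------------------------
# tabular / track output
# ---------------------------------------------------------------------------


def stop_profile_table(profile: StopProfile, bundle: ReferenceBundle) -> pd.DataFrame:
    """Long-format stop-ratio table: one row per reference position."""
    rows = []
    for ref in bundle.references:
        ratios = profile.ratio[ref.id]
        for pos in range(1, len(ref) + 1):
            rows.append(
                {
                    "trna_id": ref.id,
                    "position": pos,
                    "canonical_label": ref.label_for_index(pos) or "",
                    "n5": int(profile.n5[ref.id][pos - 1]) if profile.n5 else 0,
                    "cov": int(profile.cov[ref.id][pos - 1]) if profile.cov else 0,
                    "stop_ratio": float(ratios[pos - 1]),
                    "low_coverage": bool(profile.low_coverage[ref.id][pos - 1]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["trna_id", "position", "canonical_label", "n5", "cov", "stop_ratio", "low_coverage"],
    )


def calls_table(calls: list[DSiteCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trna_id": c.trna_id,
                "d_index": c.d_index,
                "canonical_label": c.canonical_label or "",
                "enzyme": c.enzyme or "",
                "stop_ratio": c.stop_ratio,
            }
            for c in calls
        ],
        columns=["trna_id", "d_index", "canonical_label", "enzyme", "stop_ratio"],
    )


def write_bedgraph(profile: StopProfile, path) -> None:
    """Write stop ratios as bedGraph (0-based, half-open intervals on disk)."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="stop_ratio"\n')
        for trna_id in sorted(profile.ratio):
            ratios = profile.ratio[trna_id]
            for pos0, value in enumerate(ratios):
                if value > 0:
                    fh.write(f"{trna_id}\t{pos0}\t{pos0 + 1}\t{value:.6g}\n")
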