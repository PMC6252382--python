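"""Experiment grid driver and summary artifacts.

Enumerates every (recording, condition pair, montage, feature kind) cell of a
study — 36 recordings x 7 comparisons x 4 montages = 1008 classification
accuracies per feature kind at full scale — runs the nested-CV classification
per cell with a deterministic derived seed, and reduces the resulting long
table to the standard summaries: group-wise mean accuracies, counts of
recordings above an accuracy threshold, within-class accuracy distributions
and feature-selection proportion heatmaps.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .classify import ClassifierParams, nested_classify
from .montage import MONTAGE_NAMES, MontageConfig, build_montage, make_layout
from .mvar import build_ffdtf_features, max_model_order
from .preprocessing import SegmentSet, apply_montage, segments_from_recording
from .spectral import BandScheme, FeatureTable, build_fft_features, default_band_scheme
from .synthetic import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "COMPARISONS",
    "GridCell",
    "ExperimentGrid",
    "SummaryTables",
    "build_grid",
    "run_experiment",
    "summarize",
]

#: The 7 pairwise comparisons: each imagery/movement condition vs. rest,
#: hand vs. foot within imagery and movement, and the observation control.
COMPARISONS = (
    ("IF", "RS"),
    ("IH", "RS"),
    ("MF", "RS"),
    ("MH", "RS"),
    ("IF", "IH"),
    ("MF", "MH"),
    ("OF", "OH"),
)

RESULT_COLUMNS = [
    "recording", "group", "subject", "session", "comparison", "montage",
    "feature_kind", "h0", "n", "accuracy", "sensitivity", "specificity",
    "n_features", "seed", "selected_features", "error",
]


@dataclass(frozen=True)
class GridCell:
    recording_index: int
    comparison: tuple[str, str]
    montage: str
    feature_kind: str
    seed: int

    @property
    def cell_id(self) -> str:
        return (
            f"r{self.recording_index}:{self.comparison[0]}-{self.comparison[1]}:"
            f"{self.montage}:{self.feature_kind}"
        )


@dataclass(frozen=True)
class ExperimentGrid:
    cells: tuple[GridCell, ...]

    def __len__(self) -> int:
        return len(self.cells)


def build_grid(
    n_recordings: int,
    comparisons=COMPARISONS,
    montages=MONTAGE_NAMES,
    feature_kinds=("FFT", "ffDTF"),
    seed: int = 0,
) -> ExperimentGrid:
    """Enumerate every grid cell with a unique deterministic per-cell seed."""
    if n_recordings < 1:
        raise ValueError("need at least one recording")
    rng = np.random.default_rng(seed)
    cells = []
    for r in range(n_recordings):
        for pair in comparisons:
            for montage in montages:
                for kind in feature_kinds:
                    cells.append(
                        GridCell(
                            recording_index=r,
                            comparison=tuple(pair),
                            montage=montage,
                            feature_kind=kind,
                            seed=int(rng.integers(0, 2**31 - 1)),
                        )
                    )
    return ExperimentGrid(cells=tuple(cells))


def _subset_features(table: FeatureTable, mask: np.ndarray) -> FeatureTable:
    return replace(table, values=table.values[mask])


def _resolve_montage(name: str, recording: Recording) -> MontageConfig:
    """Adapt the named montage to the recording's channel set.

    High-density montages shrink with the net; their model order is re-capped
    by the samples-per-coefficient rule when the channel count changes.
    """
    layout = make_layout(recording.n_channels)
    if tuple(layout.labels) != tuple(recording.channel_labels):
        raise ValueError("recording channels do not match a synthetic net layout")
    montage = build_montage(name, layout)
    cap = max_model_order(250, montage.n_channels)
    if montage.model_order > cap and montage.name != "LD-SM":
        montage = replace(montage, model_order=cap)
    return montage


def run_experiment(
    recordings: list[Recording],
    grid: ExperimentGrid,
    params: ClassifierParams = ClassifierParams(),
    scheme: BandScheme | None = None,
    done_cell_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Run every grid cell; one result row per cell.

    Per-cell failures are logged and recorded in the ``error`` column without
    aborting the grid.  ``done_cell_ids`` allows resuming: those cells are
    skipped.
    """
    if scheme is None:
        scheme = default_band_scheme()
    rows = []
    seg_cache: dict[tuple[int, str], SegmentSet] = {}
    feat_cache: dict[tuple[int, str, str], FeatureTable] = {}
    base_cache: dict[int, SegmentSet] = {}
    for cell in grid.cells:
        if done_cell_ids and cell.cell_id in done_cell_ids:
            continue
        rec = recordings[cell.recording_index]
        row = {
            "recording": f"{rec.subject_id or cell.recording_index}-s{rec.session}",
            "group": rec.subject_profile,
            "subject": rec.subject_id,
            "session": rec.session,
            "comparison": f"{cell.comparison[0]}-{cell.comparison[1]}",
            "montage": cell.montage,
            "feature_kind": cell.feature_kind,
            "seed": cell.seed,
            "error": "",
        }
        t0 = time.perf_counter()
        try:
            key = (cell.recording_index, cell.montage)
            if key not in seg_cache:
                if cell.recording_index not in base_cache:
                    base_cache[cell.recording_index] = segments_from_recording(rec)
                montage = _resolve_montage(cell.montage, rec)
                seg_cache[key] = apply_montage(base_cache[cell.recording_index], montage)
            segs = seg_cache[key]
            fkey = key + (cell.feature_kind,)
            if fkey not in feat_cache:
                if cell.feature_kind == "FFT":
                    feat_cache[fkey] = build_fft_features(segs, scheme)
                else:
                    montage = _resolve_montage(cell.montage, rec)
                    feat_cache[fkey] = build_ffdtf_features(segs, montage, scheme)
            table = feat_cache[fkey]
            mask = np.isin(segs.condition, list(cell.comparison))
            outcome = nested_classify(
                _subset_features(table, mask),
                segs.condition[mask],
                segs.trial_id[mask],
                cell.comparison,
                params,
                seed=cell.seed,
            )
            names = table.feature_names()
            selected = sorted(
                {names[f] for sel in outcome.selections for f in sel.consensus}
            )
            row.update(
                h0=outcome.h0, n=outcome.n, accuracy=outcome.accuracy,
                sensitivity=outcome.sensitivity, specificity=outcome.specificity,
                n_features=outcome.n_features,
                selected_features=";".join(selected),
            )
        except Exception as exc:  # keep the grid going
            logger.exception("cell %s failed", cell.cell_id)
            row.update(
                h0=np.nan, n=np.nan, accuracy=np.nan, sensitivity=np.nan,
                specificity=np.nan, n_features=np.nan, selected_features="",
                error=str(exc),
            )
        logger.info("cell %s done in %.1fs", cell.cell_id, time.perf_counter() - t0)
        rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


@dataclass(frozen=True)
class SummaryTables:
    """Summary artifacts derived from a results table."""

    mean_accuracy: pd.DataFrame
    counts_above_threshold: pd.DataFrame
    within_class: pd.DataFrame
    selection_heatmap: pd.DataFrame
    threshold: float

    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.mean_accuracy.to_csv(d / "mean_accuracy.csv")
        self.counts_above_threshold.to_csv(d / "counts_above_threshold.csv")
        self.within_class.to_csv(d / "within_class.csv", index=False)
        self.selection_heatmap.to_csv(d / "selection_heatmap.csv", index=False)


def summarize(
    results: pd.DataFrame,
    threshold: float = 0.75,
    first_session_only: bool = False,
) -> SummaryTables:
    """Reduce a results table to the standard summary artifacts.

    Patients' repeat sessions count as separate recordings unless
    ``first_session_only`` filters them out.  The threshold count uses a
    strict inequality (accuracy strictly above the threshold).
    """
    if results.empty:
        raise ValueError("results table is empty")
    df = results[results["error"].fillna("") == ""].copy()
    if first_session_only:
        df = df[df["session"] == 1]
    keys = ["group", "feature_kind", "comparison", "montage"]

    mean_accuracy = df.pivot_table(
        index=["feature_kind", "comparison"], columns=["group", "montage"],
        values="accuracy", aggfunc="mean",
    )
    above = df.assign(above=(df["accuracy"] > threshold).astype(int))
    counts = above.pivot_table(
        index=["feature_kind", "comparison"], columns=["group", "montage"],
        values="above", aggfunc="sum",
    )

    wc = []
    for _, row in df.iterrows():
        c1, c2 = row["comparison"].split("-")
        for cond, acc in ((c1, row["sensitivity"]), (c2, row["specificity"])):
            wc.append(
                {**{k: row[k] for k in keys}, "condition": cond, "accuracy": acc}
            )
    within_class = pd.DataFrame(wc)

    heat = []
    for group_keys, sub in df.groupby(keys):
        n_rec = len(sub)
        feature_counts: dict[str, int] = {}
        for sel in sub["selected_features"]:
            if not isinstance(sel, str) or not sel:
                continue
            for name in set(sel.split(";")):
                feature_counts[name] = feature_counts.get(name, 0) + 1
        for name, count in sorted(feature_counts.items()):
            heat.append(
                dict(zip(keys, group_keys))
                | {"feature": name, "proportion": count / n_rec}
            )
    selection_heatmap = pd.DataFrame(
        heat, columns=keys + ["feature", "proportion"]
    )
    return SummaryTables(
        mean_accuracy=mean_accuracy,
        counts_above_threshold=counts,
        within_class=within_class,
        selection_heatmap=selection_heatmap,
        threshold=threshold,
    )
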