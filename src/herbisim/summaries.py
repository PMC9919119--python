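"""Persistence statistics, outcome classification, and tidy CSV output.

*Persistence* of a trait allele is its frequency averaged over all
simulated generations and replicates (a grand mean over the padded
generation x replicate matrix).  Outcomes are classified per trait from
the mean frequency in the final window of a run: fixed (> 0.95), lost
(< 0.05), or polymorphic, with derived flags for mixed defense
(resistance and tolerance both present) and mixed mating (selfing
polymorphic).  Thresholds and window are arguments, not constants.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import RunResult
from .params import Params, load_config

TRAITS = ("resistance", "tolerance", "selfing", "antiresistance")

_TRAIT_COLUMNS = {
    "resistance": "freq_resistance",
    "tolerance": "freq_tolerance",
    "selfing": "freq_selfing",
    "antiresistance": "freq_antiresistance",
}


def trait_column(trait: str, selfing_mode: str = "heritable") -> str:
    """Column tracking a trait; non-heritable selfing lives in the tag fraction."""
    if trait not in _TRAIT_COLUMNS:
        raise KeyError(f"unknown trait: {trait!r} (use one of {TRAITS})")
    if trait == "selfing" and selfing_mode == "non_heritable":
        return "selfer_fraction"
    return _TRAIT_COLUMNS[trait]


def _series(run, trait: str) -> np.ndarray:
    if isinstance(run, RunResult):
        col = trait_column(trait, run.params.selfing_mode)
        return run.records[col].to_numpy(dtype=float)
    if isinstance(run, pd.DataFrame):
        return run[trait_column(trait)].to_numpy(dtype=float)
    return np.asarray(run, dtype=float)


def _padded_matrix(runs: Sequence, trait: str) -> np.ndarray:
    trait_column(trait)  # validate the trait name even for raw series input
    series = [_series(run, trait) for run in runs]
    if not series:
        raise ValueError("at least one replicate is required")
    length = max(len(s) for s in series)
    # extinct (shorter) runs are padded with their terminal frequency so the
    # statistic stays comparable across sweep cells
    return np.stack([
        np.concatenate([s, np.full(length - len(s), s[-1])]) if len(s) else
        np.full(length, np.nan)
        for s in series
    ])


def persistence(runs: Sequence, trait: str) -> float:
    """Grand mean of a trait's frequency over all generations and replicates."""
    return float(np.nanmean(_padded_matrix(runs, trait)))


@dataclasses.dataclass(frozen=True)
class OutcomeLabel:
    """Final-window state per trait plus mixed-strategy flags."""

    states: dict[str, str]   # trait -> fixed | lost | polymorphic
    mixed_defense: bool      # resistance present AND tolerance present
    mixed_mating: bool       # selfing polymorphic

    def state(self, trait: str) -> str:
        return self.states[trait]


def classify_outcome(runs: Sequence, lost_threshold: float = 0.05,
                     fixed_threshold: float = 0.95,
                     window_frac: float = 0.1) -> OutcomeLabel:
    """Classify the end state of each trait from the final-window mean."""
    states: dict[str, str] = {}
    for trait in TRAITS:
        mat = _padded_matrix(runs, trait)
        window = max(1, int(round(window_frac * mat.shape[1])))
        final = mat[:, -window:]
        mean = np.nanmean(final) if not np.isnan(final).all() else 0.0
        if mean > fixed_threshold:
            states[trait] = "fixed"
        elif mean < lost_threshold:
            states[trait] = "lost"
        else:
            states[trait] = "polymorphic"
    mixed_defense = (states["resistance"] != "lost"
                     and states["tolerance"] != "lost")
    mixed_mating = states["selfing"] == "polymorphic"
    return OutcomeLabel(states, mixed_defense, mixed_mating)


# ---------------------------------------------------------------------------
# CSV output (RFC-4180, UTF-8, dot decimal)

def write_run_csv(result: RunResult, path: str | Path) -> Path:
    """One row per generation; '#' header lines echo the Params and seed."""
    from .params import dumps_config

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in dumps_config(result.params).splitlines():
            fh.write(f"# {line}\n")
        fh.write(f"# replicate = {result.replicate}\n")
        fh.write(f"# status = {result.status}\n")
        result.records.to_csv(fh, index=False)
    return path


def read_run_csv(path: str | Path) -> RunResult:
    """Inverse of ``write_run_csv``: reproduces the in-memory series exactly."""
    import tempfile

    path = Path(path)
    header: dict[str, str] = {}
    body_start = 0
    lines = path.read_text(encoding="utf-8").splitlines(keepends=True)
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, value = line[1:].strip().partition(" = ")
        header[key.strip()] = value.strip()
    replicate = int(header.pop("replicate", "0"))
    status = header.pop("status", "completed")
    with tempfile.NamedTemporaryFile("w", suffix=".toml", delete=False) as tmp:
        tmp.write("\n".join(f"{k} = {v}" for k, v in header.items()))
        tmp_path = tmp.name
    try:
        p = load_config(tmp_path)
    finally:
        Path(tmp_path).unlink(missing_ok=True)
    records = pd.read_csv(path, comment="#")
    return RunResult(p, replicate, records, status)


def sweep_summary(cells: Mapping[str, Sequence[RunResult]],
                  grid_keys: Sequence[str] = (),
                  **classify_kwargs) -> pd.DataFrame:
    """One row per grid cell x trait: parameters, persistence, state, flags."""
    rows = []
    for label, runs in cells.items():
        outcome = classify_outcome(runs, **classify_kwargs)
        p = runs[0].params if isinstance(runs[0], RunResult) else None
        for trait in TRAITS:
            row = {"cell": label, "trait": trait,
                   "persistence": persistence(runs, trait),
                   "state": outcome.state(trait),
                   "mixed_defense": outcome.mixed_defense,
                   "mixed_mating": outcome.mixed_mating}
            if p is not None:
                for key in grid_keys:
                    row[key] = getattr(p, key)
            rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(cells: Mapping[str, Sequence[RunResult]],
                  out_dir: str | Path,
                  grid_keys: Sequence[str] = ()) -> list[Path]:
    """Write per-run generation CSVs plus a sweep summary CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, runs in cells.items():
        for run in runs:
            paths.append(write_run_csv(run, out / f"{label}_rep{run.replicate}.csv"))
    summary = sweep_summary(cells, grid_keys)
    summary_path = out / "summary.csv"
    summary.to_csv(summary_path, index=False)
    paths.append(summary_path)
    return paths
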