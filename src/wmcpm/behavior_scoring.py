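"""Working-memory capacity estimators and composite component scores.

Capacity from change detection uses Cowan's estimator K = S (H - F); tracked
capacity in multiple-object tracking uses Scholl's K = S (2P - 1). Per-task
scores are outlier-limited at the grand mean +/- 3 SD, z-scored across
subjects, and averaged into component composites (e.g. the event component is
the mean of the biological-motion and non-biological-motion composites).
These composites are the targets the connectome prediction pipeline learns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class MissingDataError(KeyError):
    """A subject lacks a score for a task required by the composite structure."""


@dataclass(frozen=True)
class TrialCounts:
    """Change-detection outcome counts for one subject × set size."""

    S: int
    hits: int
    n_change: int
    false_alarms: int
    n_nochange: int

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("set size must be >= 1")
        if not 0 <= self.hits <= self.n_change:
            raise ValueError("hits must lie in [0, n_change]")
        if not 0 <= self.false_alarms <= self.n_nochange:
            raise ValueError("false_alarms must lie in [0, n_nochange]")

    @property
    def hit_rate(self) -> float:
        return self.hits / self.n_change

    @property
    def false_alarm_rate(self) -> float:
        return self.false_alarms / self.n_nochange

    def cowan_k(self) -> float:
        return cowan_k(self.S, self.hit_rate, self.false_alarm_rate)


def cowan_k(S: int, H: float, F: float) -> float:
    """Cowan's change-detection capacity, K = S (H - F).

    Parameters
    ----------
    S : set size (items), H : hit rate, F : false-alarm rate.
    """
    if S < 1:
        raise ValueError("set size must be >= 1")
    if not (0 <= H <= 1 and 0 <= F <= 1):
        raise ValueError(f"rates must lie in [0, 1], got H={H}, F={F}")
    return S * (H - F)


def k_max(per_load_Ks: Sequence[float]) -> float:
    """A subject's capacity: the maximum K across load conditions."""
    ks = list(per_load_Ks)
    if not ks:
        raise ValueError("need at least one per-load K")
    return float(max(ks))


def scholl_k(S: int, P: float) -> float:
    """Effective number of objects tracked in MOT, K = S (2P - 1)."""
    if S < 1:
        raise ValueError("target count must be >= 1")
    if not 0 <= P <= 1:
        raise ValueError(f"tracking accuracy must lie in [0, 1], got {P}")
    return S * (2 * P - 1)


def winsorize_3sd(scores) -> np.ndarray:
    """Limit values to the grand mean +/- 3 SD of the input.

    Cutoffs are computed once from the original vector (single pass, not
    iterated). A constant vector (SD = 0) is returned unchanged: every value
    already equals the mean.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector of at least 2 scores")
    if not np.all(np.isfinite(x)):
        raise ValueError("scores must be finite")
    m, sd = x.mean(), x.std(ddof=1)
    return np.clip(x, m - 3 * sd, m + 3 * sd)


def zscore_across_subjects(values) -> np.ndarray:
    """z-score with the sample SD (n-1); constant input maps to zeros."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def composite_scores(
    task_table: pd.DataFrame,
    structure: Mapping[str, Sequence[str]],
    winsorize: bool = True,
) -> pd.DataFrame:
    """Per-subject component composites from a long task-score table.

    Parameters
    ----------
    task_table
        Long table with columns ``subject_id``, ``task``, ``score`` (one row
        per subject × task; a ``load`` column, if present, is ignored — feed
        per-load scores through :func:`k_max` first).
    structure
        Maps each component to its members. A member naming a task averages
        that task's z-score; a member naming another component (e.g.
        ``{"EVENT": ["BM", "NBM"]}``) averages the already-built composite,
        so second-order components are plain means of first-order ones.
    winsorize
        Apply the 3-SD limit to each task column before z-scoring.

    Returns
    -------
    DataFrame indexed by subject_id with one column per component.
    """
    required = {"subject_id", "task", "score"}
    if not required <= set(task_table.columns):
        raise ValueError(f"task table needs columns {sorted(required)}")
    wide = task_table.pivot_table(
        index="subject_id", columns="task", values="score", aggfunc="first"
    )
    if len(wide) < 2:
        raise ValueError("need at least 2 subjects to z-score")
    for task in wide.columns:
        nulls = wide.index[wide[task].isna()]
        if len(nulls):
            raise MissingDataError(
                f"subject {nulls[0]!r} is missing task {task!r}"
            )
    z = pd.DataFrame(index=wide.index)
    for task in wide.columns:
        col = wide[task].to_numpy()
        if winsorize:
            col = winsorize_3sd(col)
        z[task] = zscore_across_subjects(col)

    out = pd.DataFrame(index=wide.index)
    pending = dict(structure)
    while pending:
        progressed = False
        for comp in list(pending):
            members = pending[comp]
            cols = []
            ready = True
            for m in members:
                if m in z.columns:
                    cols.append(z[m].to_numpy())
                elif m in out.columns:
                    cols.append(out[m].to_numpy())
                elif m in pending:
                    ready = False
                    break
                else:
                    raise MissingDataError(
                        f"component {comp!r} references unknown member {m!r}"
                    )
            if not ready:
                continue
            if not cols:
                raise ValueError(f"component {comp!r} has no members")
            out[comp] = np.mean(cols, axis=0)
            del pending[comp]
            progressed = True
        if not progressed:
            raise ValueError(f"circular composite structure among {sorted(pending)}")
    return out


def score_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Cowan-K scores from a long trial-count table.

    Expects columns subject_id, task, load (set size), hits, n_change,
    false_alarms, n_nochange — one row per subject × task × load. Returns a
    long score table (subject_id, task, score) with each subject's capacity
    per task taken as K_max across that task's load conditions, ready for
    :func:`composite_scores`.
    """
    required = {"subject_id", "task", "load", "hits", "n_change",
                "false_alarms", "n_nochange"}
    if not required <= set(trials.columns):
        raise ValueError(f"trial table needs columns {sorted(required)}")
    ks = trials.apply(
        lambda row: TrialCounts(
            S=int(row["load"]),
            hits=int(row["hits"]),
            n_change=int(row["n_change"]),
            false_alarms=int(row["false_alarms"]),
            n_nochange=int(row["n_nochange"]),
        ).cowan_k(),
        axis=1,
    )
    per_load = trials[["subject_id", "task"]].assign(k=ks)
    out = (
        per_load.groupby(["subject_id", "task"], as_index=False)["k"]
        .max()
        .rename(columns={"k": "score"})
    )
    return out


#: the component structure used throughout: two event sub-composites feed the
#: second-order EVENT component, alongside OBJECT and central-executive (CE)
DEFAULT_STRUCTURE: dict[str, list[str]] = {
    "BM": ["pld_bm", "solid_bm"],
    "NBM": ["pld_nbm", "solid_nbm"],
    "EVENT": ["BM", "NBM"],
    "OBJECT": ["color", "shape", "location", "binding", "mot"],
    "CE": ["nback", "switching", "updating"],
}
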