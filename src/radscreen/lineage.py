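"""Rule-based fate classification of time-lapse lineage event logs.

Each lineage is an annotated log of per-cell events observed over a 48 h
movie (H2B-GFP chromatin morphology plus phase contrast):

    condensation_start      chromatin condensation, i.e. mitosis onset
    karyokinesis_complete   nuclear division finished
    cytokinesis_complete    cell cleavage finished
    daughter_fusion         two sister cells re-fuse after division
    death                   cell death, with an explicit phase_at_death label
                            ("interphase" or "mitosis")

Classification rules:

* a lineage is *surviving* when every cell in it survived, and *cell death*
  when at least one cell died, sub-classified as death in interphase or
  death in mitosis;
* when deaths occur in parallel branches, the death initiated earliest
  (event start time; ties broken by cell id) determines the sub-class;
* polyploidization is scored in surviving lineages only, either daughter
  fusion or karyokinesis without a subsequent cytokinesis;
* mitosis length runs from condensation start to cytokinesis completion,
  or to karyokinesis completion when cytokinesis never happens
  (karyokinesis-only polyploidization); it is undefined for cells that die
  during mitosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENTS = {"condensation_start", "karyokinesis_complete", "cytokinesis_complete",
          "daughter_fusion", "death"}
FATES = ("surviving", "death_interphase", "death_mitosis")
EVENT_COLUMNS = ["lineage_id", "cell_id", "parent_id", "event", "time_min",
                 "phase_at_death"]


@dataclass
class LineageFate:
    lineage_id: str
    fate: str
    polyploidization: bool
    mitosis_lengths: list = field(default_factory=list)
    scored_branch_note: str = ""


def _validate_lineage(log: pd.DataFrame) -> None:
    unknown = set(log["event"]) - EVENTS
    if unknown:
        raise ValueError(f"unknown event(s): {sorted(unknown)}")
    cells = set(log["cell_id"])
    roots = 0
    for cell, grp in log.groupby("cell_id"):
        parents = grp["parent_id"].dropna().unique()
        if len(parents) == 0:
            roots += 1
        elif parents[0] not in cells:
            raise ValueError(f"cell {cell!r} has unknown parent {parents[0]!r}")
        times = {}
        for _, row in grp.iterrows():
            times.setdefault(row["event"], row["time_min"])
        order = ["condensation_start", "karyokinesis_complete", "cytokinesis_complete"]
        present = [e for e in order if e in times]
        for a, b in zip(present, present[1:]):
            if times[b] < times[a]:
                raise ValueError(f"cell {cell!r}: {b} at {times[b]} precedes {a} at {times[a]}")
        if "karyokinesis_complete" in times and "condensation_start" not in times:
            raise ValueError(f"cell {cell!r}: karyokinesis without condensation_start")
    if roots == 0:
        raise ValueError("lineage has no root cell (all cells have parents)")
    deaths = log[log["event"] == "death"]
    bad = deaths[~deaths["phase_at_death"].isin(["interphase", "mitosis"])]
    if len(bad):
        raise ValueError("death events must carry phase_at_death in "
                         "{'interphase', 'mitosis'}")


def classify_lineage(log: pd.DataFrame) -> LineageFate:
    """Classify one lineage's event log into its fate category.

    Deterministic: events are ordered by (time, cell id), so simultaneous
    parallel-branch events resolve by the lower cell id.
    """
    _validate_lineage(log)
    lid = log["lineage_id"].iloc[0]
    log = log.sort_values(["time_min", "cell_id"], kind="mergesort")
    deaths = log[log["event"] == "death"]
    lengths = []
    for cell in log["cell_id"].unique():
        try:
            ml = mitosis_length(log, cell)
        except ValueError:
            continue
        if ml is not None:
            lengths.append(ml)
    if len(deaths):
        first = deaths.iloc[0]
        note = ""
        if len(deaths) > 1:
            note = (f"{len(deaths)} deaths; scored branch = cell "
                    f"{first['cell_id']} (initiated earliest)")
        fate = "death_interphase" if first["phase_at_death"] == "interphase" else "death_mitosis"
        return LineageFate(lineage_id=lid, fate=fate, polyploidization=False,
                           mitosis_lengths=lengths, scored_branch_note=note)
    poly = bool((log["event"] == "daughter_fusion").any())
    note = "daughter fusion" if poly else ""
    for cell, grp in log.groupby("cell_id"):
        ev = set(grp["event"])
        if "karyokinesis_complete" in ev and "cytokinesis_complete" not in ev:
            poly = True
            note = (note + "; " if note else "") + f"karyokinesis without cytokinesis ({cell})"
    return LineageFate(lineage_id=lid, fate="surviving", polyploidization=poly,
                       mitosis_lengths=lengths, scored_branch_note=note)


def mitosis_length(log: pd.DataFrame, cell_id) -> float | None:
    """Mitosis length (min) for one cell, or None if mitosis is unresolved.

    Condensation start to cytokinesis completion; when cytokinesis never
    occurs (karyokinesis-only polyploidization), completion is defined by
    karyokinesis alone.  Cells that die in mitosis, or are still mitotic at
    the end of the movie, have no defined length.
    """
    grp = log[(log["cell_id"] == cell_id)]
    if grp.empty:
        raise ValueError(f"no events for cell {cell_id!r}")
    times = {row["event"]: row["time_min"] for _, row in grp.iterrows()
             if row["event"] in EVENTS}
    if "condensation_start" not in times:
        raise ValueError(f"cell {cell_id!r} has no condensation_start event")
    if "cytokinesis_complete" in times:
        return float(times["cytokinesis_complete"] - times["condensation_start"])
    died_in_mitosis = ((grp["event"] == "death") &
                       (grp["phase_at_death"] == "mitosis")).any()
    if died_in_mitosis:
        return None
    if "karyokinesis_complete" in times:
        return float(times["karyokinesis_complete"] - times["condensation_start"])
    return None


def classify_lineages(events: pd.DataFrame) -> pd.DataFrame:
    """Classify every lineage in an event table; one row per lineage."""
    rows = []
    for _, log in events.groupby("lineage_id", sort=True):
        fate = classify_lineage(log)
        rows.append({"lineage_id": fate.lineage_id, "fate": fate.fate,
                     "polyploidization": fate.polyploidization,
                     "n_mitoses": len(fate.mitosis_lengths),
                     "scored_branch_note": fate.scored_branch_note})
    return pd.DataFrame(rows)


def summarize_fates(fates: pd.DataFrame) -> dict:
    """Percentage of lineages per fate plus the polyploidization rate.

    Percentages sum to 100 over the three fate categories; polyploidization
    is reported as a percentage of *surviving* lineages.
    """
    if len(fates) == 0:
        raise ValueError("no lineages to summarize")
    n = len(fates)
    out = {f"{fate}_pct": 100.0 * float((fates["fate"] == fate).sum()) / n
           for fate in FATES}
    surviving = fates[fates["fate"] == "surviving"]
    out["polyploidization_pct_of_surviving"] = (
        100.0 * float(surviving["polyploidization"].sum()) / len(surviving)
        if len(surviving) else float("nan"))
    out["n_lineages"] = n
    return out


def read_lineage_events(path) -> pd.DataFrame:
    """Read a ``lineage_events.csv`` table (see EVENT_COLUMNS)."""
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    return df


def write_lineage_events(events: pd.DataFrame, path) -> None:
    events[EVENT_COLUMNS].to_csv(path, index=False, encoding="utf-8")
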