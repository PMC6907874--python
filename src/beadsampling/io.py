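"""Dataset files: a CSV triplet (trials, samples, participants).

trials.csv       one row per trial: participant, trial, block,
                 permutation_id, cost, q, hidden_jar, jar_side, n_samples,
                 judgment, correct
samples.csv      one row per sampling choice: participant, trial, j (1-based
                 sample index), bead (P/B), choice (continue/stop), dt
participants.csv one row per participant: participant, aq, optional
                 age/gender/iq and ground-truth columns

All tables are comma-separated UTF-8 with a header row; booleans are 0/1.
``read_dataset`` validates referential integrity and the task invariants
(sample counts, bead codes, positive DTs) and reports violations with row
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import AgentProfile
from .task import MAX_SAMPLES, Condition, TrialRecord

TRIALS_COLUMNS = [
    "participant",
    "trial",
    "block",
    "cost",
    "q",
    "hidden_jar",
    "jar_side",
    "n_samples",
    "judgment",
    "correct",
]
SAMPLES_COLUMNS = ["participant", "trial", "j", "bead", "dt"]
PARTICIPANTS_COLUMNS = ["participant", "aq"]


@dataclass
class Dataset:
    """In-memory dataset: per-participant trial lists plus the AQ table."""

    participants: dict[str, list[TrialRecord]]
    participant_table: pd.DataFrame

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def aq_scores(self) -> dict[str, float]:
        return dict(
            zip(
                self.participant_table["participant"],
                self.participant_table["aq"].astype(float),
            )
        )


def dataset_paths(directory: str | Path) -> dict[str, Path]:
    d = Path(directory)
    return {
        "trials": d / "trials.csv",
        "samples": d / "samples.csv",
        "participants": d / "participants.csv",
    }


def write_dataset(
    participants: Mapping[str, Sequence[TrialRecord]],
    directory: str | Path,
    profiles: Sequence[AgentProfile] | None = None,
    participant_table: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the CSV triplet (plus ground truth when profiles are given)."""
    paths = dataset_paths(directory)
    Path(directory).mkdir(parents=True, exist_ok=True)
    trial_rows, sample_rows = [], []
    for pid in sorted(participants):
        for t in participants[pid]:
            trial_rows.append(
                {
                    "participant": pid,
                    "trial": t.trial_index,
                    "block": t.block_index,
                    "cost": t.condition.unit_cost,
                    "q": t.condition.q,
                    "hidden_jar": t.hidden_jar,
                    "jar_side": t.jar_side,
                    "n_samples": t.n_samples,
                    "judgment": t.judgment,
                    "correct": int(t.correct),
                }
            )
            for j, (bead, dt) in enumerate(zip(t.beads, t.choice_dts), 1):
                sample_rows.append(
                    {
                        "participant": pid,
                        "trial": t.trial_index,
                        "j": j,
                        "bead": bead,
                        "dt": dt,
                    }
                )
    pd.DataFrame(trial_rows, columns=TRIALS_COLUMNS).to_csv(
        paths["trials"], index=False
    )
    pd.DataFrame(sample_rows, columns=SAMPLES_COLUMNS).to_csv(
        paths["samples"], index=False
    )
    if participant_table is None:
        if profiles is not None:
            participant_table = pd.DataFrame(
                [
                    {
                        "participant": p.agent_id,
                        "aq": p.aq,
                        "pi_costfirst": p.pi_costfirst,
                        "psec_zero": p.p_sec[0],
                        "psec_low": p.p_sec[1],
                        "psec_high": p.p_sec[2],
                        "alpha": p.alpha,
                        "seed": p.seed,
                    }
                    for p in profiles
                ]
            )
        else:
            participant_table = pd.DataFrame(
                {"participant": sorted(participants), "aq": np.nan}
            )
    participant_table.to_csv(paths["participants"], index=False)
    return paths


class DatasetError(ValueError):
    pass


def read_dataset(directory: str | Path) -> Dataset:
    """Read and validate the CSV triplet from a directory."""
    paths = dataset_paths(directory)
    for name, p in paths.items():
        if not p.exists():
            raise DatasetError(f"missing {name} table: {p}")
    trials = pd.read_csv(paths["trials"])
    samples = pd.read_csv(paths["samples"])
    ptable = pd.read_csv(paths["participants"])
    for cols, df, name in [
        (TRIALS_COLUMNS, trials, "trials"),
        (SAMPLES_COLUMNS, samples, "samples"),
        (PARTICIPANTS_COLUMNS, ptable, "participants"),
    ]:
        missing = set(cols) - set(df.columns)
        if missing:
            raise DatasetError(f"{name}.csv lacks columns {sorted(missing)}")

    known = set(ptable["participant"].astype(str))
    bad = samples[samples["j"] > MAX_SAMPLES]
    if len(bad):
        raise DatasetError(
            f"samples.csv rows {list(bad.index + 2)}: sample index exceeds "
            f"{MAX_SAMPLES}"
        )
    bad = samples[samples["dt"] <= 0]
    if len(bad):
        raise DatasetError(
            f"samples.csv rows {list(bad.index + 2)}: non-positive dt"
        )
    bad = trials[~trials["participant"].astype(str).isin(known)]
    if len(bad):
        ids = sorted(set(bad["participant"].astype(str)))
        raise DatasetError(
            f"trials.csv references participants missing from "
            f"participants.csv: {ids}"
        )

    sample_groups = {
        key: grp.sort_values("j")
        for key, grp in samples.groupby(["participant", "trial"])
    }
    participants: dict[str, list[TrialRecord]] = {}
    prev_state: dict[str, tuple[float, int]] = {}
    for row_no, row in enumerate(
        trials.sort_values(["participant", "trial"]).itertuples(), start=2
    ):
        pid = str(row.participant)
        grp = sample_groups.get((row.participant, row.trial))
        beads = list(grp["bead"]) if grp is not None else []
        dts = list(grp["dt"].astype(float)) if grp is not None else []
        if len(beads) != int(row.n_samples):
            raise DatasetError(
                f"trials.csv row for participant {pid} trial {row.trial}: "
                f"n_samples={row.n_samples} but {len(beads)} sample rows"
            )
        pc, pn = prev_state.get(pid, (0.5, 0))
        rec = TrialRecord(
            participant_id=pid,
            trial_index=int(row.trial),
            block_index=int(row.block),
            condition=Condition(float(row.cost), float(row.q)),
            hidden_jar=str(row.hidden_jar),
            jar_side=str(row.jar_side),
            beads=beads,
            choice_dts=dts,
            judgment=str(row.judgment),
            correct=bool(row.correct),
            prev_correct=pc,
            prev_n=pn,
        )
        participants.setdefault(pid, []).append(rec)
        prev_state[pid] = (1.0 if rec.correct else 0.0, rec.n_samples)
    return Dataset(participants=participants, participant_table=ptable)
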