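"""RDD fieldwork simulation: number draws, call attempts, Kish selection.

The process model mirrors CATI practice for a dual-frame telephone survey:

* a simple random sample of numbers is drawn without replacement from each
  frame (default dialing budget split 40% landline / 60% cell);
* identified non-working numbers are coded ineligible (NE); numbers that are
  never answered within the attempt cap stay of unknown eligibility (UH for
  the landline frame, UO for the cell frame);
* on the cell frame the interviewee is the number's owner (one-stage design);
* on the landline frame the member who picks up is drawn from the household,
  then the interviewee is drawn by the Kish method -- equal probability
  1/e among the household's eligible members -- and a handoff call is needed
  whenever the Kish selectee is not the answerer (two-stage design);
* contact follows a geometric per-call answer process truncated at
  ``max_call_attempts``; cooperation, refusal, partial interviews and "other"
  outcomes are Bernoulli per the population's response propensities.

Outcomes are coded with AAPOR-style dispositions (I, P, R, NC, O, UH, UO, NE)
so response rates can be computed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .synthetic import FrameSpec, HEALTH_INDICATORS, PopulationConfig

DISPOSITION_CODES = ("I", "P", "R", "NC", "O", "UH", "UO", "NE")

#: Respondent-record columns carried through from the person record.
_PERSON_COLUMNS = [
    "person_id", "household_id", "sex", "age_band", "age", "sex_age",
    "education", "household_size", "urbanization", "region", "phone_class",
    *HEALTH_INDICATORS,
]


@dataclass
class FieldworkConfig:
    """Dialing budget and call-process parameters for one survey wave."""

    n_landline: int = 4000
    n_cell: int = 6000
    max_call_attempts: int = 12
    handoff_prob: float = 0.85      # reach the Kish selectee when not the answerer
    partial_prob: float = 0.02      # partial interview given cooperation
    other_prob: float = 0.01        # contact resolved "other" (language, incapacity)
    nonworking_identified_prob: float = 0.80  # non-working number yields a tritone
    seed: int = 0

    def validate(self, frames: FrameSpec | None = None) -> None:
        if self.max_call_attempts < 1:
            raise ConfigError("max_call_attempts must be >= 1")
        if self.n_landline < 0 or self.n_cell < 0:
            raise ConfigError("dialing budgets must be >= 0")
        for name in ("handoff_prob", "partial_prob", "other_prob",
                     "nonworking_identified_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} outside [0, 1]")
        if frames is not None:
            if self.n_landline > frames.N_ll:
                raise ConfigError(
                    f"n_landline={self.n_landline} exceeds frame size {frames.N_ll}")
            if self.n_cell > frames.N_cell:
                raise ConfigError(
                    f"n_cell={self.n_cell} exceeds frame size {frames.N_cell}")

    def with_seed(self, seed: int) -> "FieldworkConfig":
        return replace(self, seed=seed)


def draw_numbers(frames: FrameSpec, config: FieldworkConfig,
                 rng: np.random.Generator | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Equal-probability draw without replacement of numbers from each frame."""
    config.validate(frames)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dialed_ll = rng.choice(frames.N_ll, size=config.n_landline, replace=False)
    dialed_cell = rng.choice(frames.N_cell, size=config.n_cell, replace=False)
    return np.sort(dialed_ll), np.sort(dialed_cell)


def kish_select(eligible_ids, rng: np.random.Generator):
    """Kish within-household selection: one eligible member, uniformly."""
    eligible_ids = list(eligible_ids)
    if not eligible_ids:
        raise DataError("Kish selection on a household with no eligible member")
    return eligible_ids[int(rng.integers(len(eligible_ids)))]


def _truncated_geometric_attempts(p: np.ndarray, cap: int,
                                  rng: np.random.Generator
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Attempt count of first answer for per-call probability p, capped.

    Returns (answered, attempts) where attempts is the answering call for
    answered numbers and ``cap`` for never-answered ones.
    """
    k = rng.geometric(np.clip(p, 1e-12, 1.0))
    answered = (k <= cap) & (p > 0)
    return answered, np.where(answered, k, cap)


def simulate_calls(frames: FrameSpec, persons: pd.DataFrame,
                   config: FieldworkConfig,
                   pop_config: PopulationConfig | None = None,
                   rng: np.random.Generator | None = None,
                   return_call_log: bool = False):
    """Run the dialing process and return respondents plus dispositions.

    Returns ``(respondents, dispositions)`` or, with ``return_call_log``,
    ``(respondents, dispositions, call_log)``. ``respondents`` has one row per
    complete interview with the frame of origin, reported multiplicities
    (t_ll, t_cell), eligible counts (e_ll, e_cell = 1), demographics and
    health responses. ``dispositions`` has one row per (frame, code) count.
    """
    config.validate(frames)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    misreport = pop_config.misreport_rate if pop_config is not None else 0.0

    dialed_ll, dialed_cell = draw_numbers(frames, config, rng)
    by_id = persons.set_index("person_id")
    hh_members = persons.groupby("household_id").indices

    rows: list[dict] = []
    log: list[dict] = []
    disp = {("landline", c): 0 for c in DISPOSITION_CODES}
    disp.update({("cell", c): 0 for c in DISPOSITION_CODES})

    # ------------------------------------------------------------- landline
    ll_frame = frames.landline.iloc[dialed_ll]
    nonworking = ll_frame["household_id"].isna().to_numpy()
    n_nw = int(nonworking.sum())
    identified = rng.random(n_nw) < config.nonworking_identified_prob
    disp[("landline", "NE")] += int(identified.sum())
    disp[("landline", "UH")] += int(n_nw - identified.sum())

    working = ll_frame.loc[~nonworking]
    contact_ll_arr = persons["contact_ll"].to_numpy()
    coop_arr = persons["coop"].to_numpy()
    pid_arr = persons["person_id"].to_numpy()
    for number_id, hid in zip(working["number_id"].to_numpy(),
                              working["household_id"].to_numpy()):
        members = hh_members[hid]
        p_answer = float(contact_ll_arr[members].mean())
        answered, attempts = _truncated_geometric_attempts(
            np.array([p_answer]), config.max_call_attempts, rng)
        attempts = int(attempts[0])
        if not answered[0]:
            disp[("landline", "UH")] += 1
            code = "UH"
        else:
            answerer = members[int(rng.integers(len(members)))]
            selectee = members[int(rng.integers(len(members)))]  # Kish: uniform
            reached = True
            if selectee != answerer:
                attempts += 1
                reached = rng.random() < config.handoff_prob
            if not reached:
                disp[("landline", "NC")] += 1
                code = "NC"
            elif rng.random() < config.other_prob:
                disp[("landline", "O")] += 1
                code = "O"
            elif rng.random() >= coop_arr[selectee]:
                disp[("landline", "R")] += 1
                code = "R"
            elif rng.random() < config.partial_prob:
                disp[("landline", "P")] += 1
                code = "P"
            else:
                disp[("landline", "I")] += 1
                code = "I"
                rows.append(_respondent_row(by_id, pid_arr[selectee],
                                            "landline", attempts, misreport, rng))
        if return_call_log:
            log.append({"frame": "landline", "number_id": int(number_id),
                        "attempts": attempts, "code": code})

    # ----------------------------------------------------------------- cell
    cell_frame = frames.cell.iloc[dialed_cell]
    nonworking = cell_frame["person_id"].isna().to_numpy()
    n_nw = int(nonworking.sum())
    identified = rng.random(n_nw) < config.nonworking_identified_prob
    disp[("cell", "NE")] += int(identified.sum())
    disp[("cell", "UO")] += int(n_nw - identified.sum())

    working = cell_frame.loc[~nonworking]
    owners = working["person_id"].astype(int).to_numpy()
    p_answer = by_id["contact_cell"].to_numpy()[owners]
    answered, attempts = _truncated_geometric_attempts(
        p_answer, config.max_call_attempts, rng)
    coop = rng.random(owners.size) < by_id["coop"].to_numpy()[owners]
    other = rng.random(owners.size) < config.other_prob
    partial = rng.random(owners.size) < config.partial_prob
    for i, (number_id, pid) in enumerate(zip(working["number_id"].to_numpy(), owners)):
        if not answered[i]:
            disp[("cell", "UO")] += 1
            code = "UO"
        elif other[i]:
            disp[("cell", "O")] += 1
            code = "O"
        elif not coop[i]:
            disp[("cell", "R")] += 1
            code = "R"
        elif partial[i]:
            disp[("cell", "P")] += 1
            code = "P"
        else:
            disp[("cell", "I")] += 1
            code = "I"
            rows.append(_respondent_row(by_id, pid, "cell", int(attempts[i]),
                                        misreport, rng))
        if return_call_log:
            log.append({"frame": "cell", "number_id": int(number_id),
                        "attempts": int(attempts[i]), "code": code})

    respondents = pd.DataFrame(
        rows, columns=_PERSON_COLUMNS + ["frame", "t_ll", "t_cell", "e_ll",
                                         "e_cell", "attempts"])
    dispositions = pd.DataFrame(
        [{"frame": f, "code": c, "count": disp[(f, c)]}
         for f in ("landline", "cell") for c in DISPOSITION_CODES])

    if return_call_log:
        return respondents, dispositions, pd.DataFrame(log)
    return respondents, dispositions


def _respondent_row(by_id: pd.DataFrame, person_id: int, frame: str,
                    attempts: int, misreport_rate: float,
                    rng: np.random.Generator) -> dict:
    person = by_id.loc[person_id]
    t_ll = int(person["n_landline"])
    t_cell = int(person["n_cell"])
    if misreport_rate > 0.0:
        if t_ll > 0 and rng.random() < misreport_rate:
            t_ll = max(1, t_ll + (1 if rng.random() < 0.5 else -1))
        if t_cell > 0 and rng.random() < misreport_rate:
            t_cell = max(1, t_cell + (1 if rng.random() < 0.5 else -1))
    row = {"person_id": int(person_id), "frame": frame,
           "t_ll": t_ll, "t_cell": t_cell,
           "e_ll": int(person["e_ll"]), "e_cell": 1, "attempts": attempts}
    for col in _PERSON_COLUMNS:
        if col != "person_id":
            row[col] = person[col]
    return row


def dispositions_by_frame(dispositions: pd.DataFrame, frame: str) -> dict[str, int]:
    """Disposition counts for one frame as a {code: count} dict."""
    sub = dispositions.loc[dispositions["frame"] == frame]
    if sub.empty:
        raise DataError(f"no dispositions for frame '{frame}'")
    return dict(zip(sub["code"], sub["count"].astype(int)))
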