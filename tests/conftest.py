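import numpy as np
import pandas as pd
import pytest

from caretraj import simulate, trajectories


@pytest.fixture(scope="session")
def small_cohort():
    """Default-configuration cohort, n=1000, with index dates."""
    cfg = simulate.default_config(n_children=1000, seed=11)
    sim = simulate.sample_cohort(cfg)
    idx = pd.Series(sim.visits.groupby("child_id")["visit_date"].min())
    return cfg, sim, idx


@pytest.fixture(scope="session")
def coded_cohort(small_cohort):
    """Trajectory matrix + per-child service-use summaries for n=1000."""
    _, sim, idx = small_cohort
    X = trajectories.trajectory_matrix(sim.visits, idx)
    summaries = trajectories.summarize_cohort(sim.visits, idx)
    return sim, X, summaries


def build_attrition_toy(n_total=12643, n_under5=3099, n_over13=2711,
                        n_pdd=841, n_prior_eoc=360):
    """Toy raw tables with disjoint exclusion strata.

    All children have one face-to-face visit inside the 2004-2006 intake
    window; the four exclusion strata are marked by age at index, a
    developmental-disorder program flag, or a complete 3-visit episode of
    care ending shortly before the intake window opens (with the index
    visit far enough after it to keep its 548-day lookback clean).
    """
    index_date = np.datetime64("2005-06-01")
    rows_children, rows_visits = [], []
    n_clean = n_total - n_under5 - n_over13 - n_pdd - n_prior_eoc
    strata = (["under5"] * n_under5 + ["over13"] * n_over13
              + ["pdd"] * n_pdd + ["prior"] * n_prior_eoc
              + ["clean"] * n_clean)
    for cid, stratum in enumerate(strata):
        age = {"under5": 3, "over13": 15}.get(stratum, 9)
        dob = index_date - np.timedelta64(int(age * 365.25) + 10, "D")
        rows_children.append({"child_id": cid, "dob": dob,
                              "sex": "M" if cid % 2 else "F",
                              "pdd_flag": int(stratum == "pdd")})
        rows_visits.append({"child_id": cid, "visit_date": index_date,
                            "contact_mode": "face_to_face",
                            "program_tag": ""})
        if stratum == "prior":
            # episode of 3 visits ending 100 days before the window start
            # (2004-01-01) and 548+100 days before this child's index visit
            window_start = np.datetime64("2004-01-01")
            end = window_start - np.timedelta64(100, "D")
            for off in (40, 20, 0):
                rows_visits.append({
                    "child_id": cid,
                    "visit_date": end - np.timedelta64(off, "D"),
                    "contact_mode": "face_to_face", "program_tag": ""})
    return (pd.DataFrame(rows_children), pd.DataFrame(rows_visits),
            ("2004-01-01", "2006-12-31"))
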