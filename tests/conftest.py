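import numpy as np
import pytest

from tbpopk.data import Cohort, DoseEvent, Observation, SubjectRecord


def make_subject(sid="S1", group="outpatient", sex="male", weight=56.0,
                 height=1.70, brc=6.0, dose_times=(-48.0, -24.0, 0.0),
                 amount=600.0, obs=None):
    rec = SubjectRecord(
        subject_id=sid, group=group, sex=sex, weight=weight, height=height,
        age=35.0, conjugated_bilirubin=brc,
    )
    for t in dose_times:
        rec.doses.append(DoseEvent(time=t, amount=amount))
    for t, v, blq in obs or []:
        rec.observations.append(Observation(time=t, value=v, blq=blq, lloq=0.117))
    return rec


@pytest.fixture
def rif_cohort_two_subjects():
    obs = [(0.0, 0.25, False), (1.0, 6.2, False), (2.5, 8.0, False),
           (4.0, 6.8, False), (6.0, 5.0, False), (8.0, 3.7, False)]
    return Cohort(drug="rifampicin", subjects=[
        make_subject("S1", obs=list(obs)),
        make_subject("S2", sex="female", height=1.60, obs=list(obs)),
    ])


@pytest.fixture(scope="session")
def small_sim_study():
    """A small simulated rifampicin study reused by the slower tests."""
    from tbpopk.data import preprocess
    from tbpopk.simulate import CohortSpec, GroupSpec, generate_cohort, simulate_trial
    from tbpopk.structural import default_params, final_model
    import dataclasses

    base = CohortSpec()
    groups = {g: dataclasses.replace(s, n=n, n_missing_height=0, n_missing_brc=0)
              for (g, s), n in zip(base.groups.items(), (10, 8, 4))}
    spec = dataclasses.replace(base, groups=groups)
    struct = final_model("rifampicin")
    pop = default_params("rifampicin")
    trial = simulate_trial(struct, pop, generate_cohort(spec, "rifampicin", 42), 123)
    return dict(trial=trial, cohort=preprocess(trial.cohort), struct=struct, pop=pop)
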