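import pandas as pd
import pytest

from tbs.cohort import generate_cohort, sample_anthropometrics

FS = 10240.0


@pytest.fixture(scope="session")
def two_subject_cohort():
    """Two Non-OSA subjects with nose+mouth recordings."""
    recordings, metadata = generate_cohort({"Non": 2}, seed=42)
    return recordings, metadata


@pytest.fixture(scope="session")
def study_size_metadata():
    """Anthropometric table with the reference cohort's class sizes
    (74 Non / 35 Mild / 50 Moderate / 40 Severe = 199 subjects)."""
    rows = []
    for i, (sev, n) in enumerate(
            {"Non": 74, "Mild": 35, "Moderate": 50, "Severe": 40}.items()):
        for r in sample_anthropometrics(sev, n, seed=100 + i):
            rows.append(dict(subject_id=r.subject_id, severity=r.severity,
                             ahi=r.ahi, age=r.age, sex=r.sex, bmi=r.bmi,
                             nc=r.nc, mps=r.mps))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def pair_acoustics():
    """Extracted acoustics for a small Non/Severe contrast (4+4 subjects)."""
    from tbs.features import extract_subject_acoustics

    recordings, metadata = generate_cohort({"Non": 4, "Severe": 4}, seed=21)
    acoustics = {}
    for sid in metadata["subject_id"]:
        acoustics[sid] = extract_subject_acoustics(
            {r: recordings[(sid, r)] for r in ("nose", "mouth")}, FS,
            subject_id=sid)
    return acoustics, metadata


@pytest.fixture(scope="session")
def e2e_report():
    """Full-default pipeline on a 40-subject cohort (10 per class), k=2.

    Session-scoped: this is the expensive end-to-end evaluation shared by the
    acceptance test and the behavioural assertions on its report.
    """
    import time
    import warnings

    from tbs.evaluation import PipelineConfig, evaluate_pipeline

    recordings, metadata = generate_cohort(
        {"Non": 10, "Mild": 10, "Moderate": 10, "Severe": 10}, seed=7)
    t0 = time.time()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = evaluate_pipeline(recordings, metadata,
                                   config=PipelineConfig(k=2), seed=11)
    report["elapsed_s"] = time.time() - t0
    return report
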