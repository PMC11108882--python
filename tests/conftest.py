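import numpy as np
import pytest

from gazebias import ScreenGeometry, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def geometry():
    return ScreenGeometry()


@pytest.fixture(scope="session")
def small_cohort():
    """Noisy synthetic cohort, 10 participants per age year 5-65."""
    cfg = SyntheticConfig(counts_per_age=10, seed=7)
    return generate_cohort(cfg)


def make_fixation_rows(pid, age, gender, starts, xs_px=None, ys_px=None):
    """CSV rows for one participant; positions default to screen center."""
    rows = []
    for i, start in enumerate(starts):
        x = xs_px[i] if xs_px is not None else 960.0
        y = ys_px[i] if ys_px is not None else 540.0
        rows.append(f"{pid},{age},{gender},{i + 1},{start},250,{x},{y}")
    return rows


HEADER = "participant_id,age_years,gender,fix_index,start_ms,duration_ms,x_px,y_px"


@pytest.fixture
def inclusion_csv(tmp_path):
    """Hand-built 12-participant table exercising every inclusion rule.

    Expected after trimming (keep 9) and inclusion (ages 5-65, >=9 fixations):
    included = 6, excluded for age = 3, excluded for too few fixations = 3.
    """
    post9 = [100 * k for k in range(9)]
    rows = [HEADER]
    rows += make_fixation_rows("p01", 30, "female", post9)  # included
    rows += make_fixation_rows("p02", 30, "male", post9[:8])  # too few (8)
    rows += make_fixation_rows("p03", 4, "male", post9)  # age below
    rows += make_fixation_rows("p04", 66, "female", post9)  # age above
    rows += make_fixation_rows("p05", 5, "male", post9)  # included (lower bound)
    rows += make_fixation_rows("p06", 65, "female", post9)  # included (upper bound)
    rows += make_fixation_rows("p07", 30, "male", [-150] + post9 + [900])  # incl: 10 post
    rows += make_fixation_rows("p08", 30, "female", [-150] + post9[:8])  # 8 post: too few
    rows += make_fixation_rows("p09", 40, "male", [100 * k for k in range(12)])  # incl
    rows += make_fixation_rows("p10", 20, "female", [-400, -300, -200])  # 0 post: too few
    rows += make_fixation_rows("p11", 0, "male", post9)  # age below
    rows += make_fixation_rows("p12", 30, "other/unknown", post9)  # included
    path = tmp_path / "inclusion_fixture.csv"
    path.write_text("\n".join(rows) + "\n")
    return path


EXPECTED_TALLY = {"included": 6, "age": 3, "too few fixations": 3}
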