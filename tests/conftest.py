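import pytest

from troughvar.data import Cohort, TroughTrajectory


def make_trajectory(concentrations, pid="p1", cohort="pre"):
    return TroughTrajectory(pid, cohort, tuple(float(c) for c in concentrations))


def make_cohort(trajs, label="pre"):
    return Cohort(
        label,
        tuple(
            make_trajectory(c, pid=f"{label}-{i}", cohort=label)
            for i, c in enumerate(trajs)
        ),
    )


@pytest.fixture
def oscillating_trajectory():
    # mean 19, full-amplitude oscillation between 8 and 30
    return make_trajectory([8.0, 30.0, 8.0, 30.0])


@pytest.fixture
def small_cohort():
    return make_cohort([[10, 16, 22], [15, 15, 15, 15], [8, 30, 8, 30]])


@pytest.fixture
def trough_csv(tmp_path):
    """Write a tidy trough table and return its path."""

    def _write(rows, columns=("patient_id", "cohort", "seq_index", "trough_mg_per_l")):
        path = tmp_path / "troughs.csv"
        lines = [",".join(columns)]
        lines += [",".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
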