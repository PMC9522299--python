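import numpy as np
import pandas as pd
import pytest

from idprel import (
    GeneratorConfig,
    IDPTable,
    Manufacturer,
    SessionInfo,
    SubjectBySessionMatrix,
    default_travelling_heads_sessions,
    generate_travelling_heads,
    specs_for_icc,
)

FOUR_SITES = ("CAM", "KCL", "LIV", "OXF")


def make_matrix(values, idp_name="idp_a") -> SubjectBySessionMatrix:
    """Wrap a 2-D array as a complete-case subject-by-session matrix."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    return SubjectBySessionMatrix(
        values=values,
        subject_ids=tuple(f"S{i + 1}" for i in range(n)),
        session_labels=tuple(f"sess{j + 1}" for j in range(k)),
        idp_name=idp_name,
    )


def make_table(values_by_idp, sessions=FOUR_SITES, class_map=None) -> IDPTable:
    """Build an IDPTable from {idp_name: n x k array (NaN = missing)}."""
    rows = []
    for idp, values in values_by_idp.items():
        values = np.asarray(values, dtype=float)
        for i in range(values.shape[0]):
            for j, sess in enumerate(sessions):
                rows.append(
                    {
                        "subject_id": f"S{i + 1}",
                        "session_label": sess,
                        "idp_name": idp,
                        "value": values[i, j],
                    }
                )
    info = [
        SessionInfo(s, manufacturer=Manufacturer.GE if s == "KCL" else Manufacturer.SIEMENS)
        for s in sessions
    ]
    return IDPTable(pd.DataFrame(rows), sessions=info, class_map=class_map)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def fixture_8x4(rng):
    """A well-conditioned 8 x 4 matrix with subject and session structure."""
    values = (
        rng.normal(0, 1.5, (8, 1))
        + np.array([0.0, 0.4, -0.2, 0.9])
        + rng.normal(0, 0.7, (8, 4))
    )
    return make_matrix(values)


@pytest.fixture
def travelling_table():
    """50-IDP synthetic travelling-heads cohort with a mild GE effect."""
    config = GeneratorConfig(
        n_subjects=8,
        sessions=default_travelling_heads_sessions(ge_offset=0.8, ge_scale=1.4),
        idp_specs=specs_for_icc(50, 0.8, "volumes", prefix="vol"),
        seed=77,
    )
    return generate_travelling_heads(config)
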