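"""Synthetic travelling-heads and test-retest cohorts with known truth.

The generative model per phenotype is the two-way layout the analysis
assumes::

    y_ij = mu + b_j + s_j * (a_i + e_ij)

with ``a_i ~ N(0, sigma_subject^2)`` a subject effect shared across sessions,
``e_ij ~ N(0, sigma_error^2)`` independent noise, ``b_j`` an additive site
offset and ``s_j > 0`` a multiplicative site scale. The scale multiplies both
the subject effect and the noise: this is the minimal model in which a scale
change perturbs sphericity (unequal variances of session differences) while
preserving the within-site ranking of subjects, the signature attributed to
manufacturer differences. With all scales equal the consistency ICC of the
phenotype is exactly ``sigma_subject^2 / (sigma_subject^2 + sigma_error^2)``
(:func:`theoretical_icc`), which anchors the parameter-recovery tests.

Missing acquisitions are completely at random: each (subject, session)
record of each phenotype is independently dropped with ``missing_rate``,
mirroring an operational cause (scanner failure) rather than anything
value-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .tables import IDPTable, Manufacturer, SessionInfo


@dataclass(frozen=True)
class SiteEffectSpec:
    """Additive offset and multiplicative scale for one session/site."""

    session_label: str
    offset: float = 0.0
    scale: float = 1.0
    manufacturer: Manufacturer = Manufacturer.SIEMENS
    site_name: str = ""
    scanner_model: str = ""

    def __post_init__(self):
        if not self.scale > 0:
            raise ConfigurationError(f"scale must be > 0, got {self.scale}")


@dataclass(frozen=True)
class IdpSpec:
    """One phenotype: grand mean and the two variance components."""

    idp_name: str
    class_label: str = "unclassified"
    mu: float = 0.0
    sigma_subject: float = 1.0
    sigma_error: float = 1.0

    def __post_init__(self):
        if self.sigma_subject < 0 or self.sigma_error < 0:
            raise ConfigurationError("standard deviations must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    n_subjects: int
    sessions: tuple
    idp_specs: tuple
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if not self.sessions:
            raise ConfigurationError("at least one session required")
        if not self.idp_specs:
            raise ConfigurationError("at least one idp_spec required")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        object.__setattr__(self, "sessions", tuple(self.sessions))
        object.__setattr__(self, "idp_specs", tuple(self.idp_specs))


def theoretical_icc(spec: IdpSpec) -> float:
    """Consistency ICC implied by the variance components.

    ``sigma_subject^2 / (sigma_subject^2 + sigma_error^2)``; by convention 1
    when ``sigma_error == 0`` (noise-free measurements repeat exactly).
    """
    if spec.sigma_error == 0:
        return 1.0
    s2, e2 = spec.sigma_subject**2, spec.sigma_error**2
    return s2 / (s2 + e2)


def default_travelling_heads_sessions(
    ge_offset: float = 0.0, ge_scale: float = 1.0
) -> tuple:
    """The 4-site layout: three Siemens sites plus one GE site.

    ``ge_offset``/``ge_scale`` inject a manufacturer effect at the GE-like
    site; the Siemens sites are null (offset 0, scale 1).
    """
    return (
        SiteEffectSpec("CAM", manufacturer=Manufacturer.SIEMENS, site_name="Cambridge"),
        SiteEffectSpec("OXF", manufacturer=Manufacturer.SIEMENS, site_name="Oxford"),
        SiteEffectSpec("LIV", manufacturer=Manufacturer.SIEMENS, site_name="Liverpool"),
        SiteEffectSpec(
            "KCL",
            offset=ge_offset,
            scale=ge_scale,
            manufacturer=Manufacturer.GE,
            site_name="London",
        ),
    )


def _subject_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"sub{i + 1:0{width}d}" for i in range(n)]


def generate_travelling_heads(config: GeneratorConfig) -> IDPTable:
    """Simulate a travelling-heads cohort table from a config.

    Fully reproducible from ``config.seed``: the same config yields a
    byte-identical table. Records are emitted in (idp, subject, session)
    order; missing acquisitions appear as NaN-valued rows so the designed
    layout stays visible in the output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    k = len(config.sessions)
    subjects = _subject_ids(n)
    labels = [s.session_label for s in config.sessions]
    offsets = np.array([s.offset for s in config.sessions])
    scales = np.array([s.scale for s in config.sessions])

    frames = []
    for spec in config.idp_specs:
        a = rng.normal(0.0, spec.sigma_subject, size=n)
        e = rng.normal(0.0, spec.sigma_error, size=(n, k))
        y = spec.mu + offsets + scales * (a[:, None] + e)
        if config.missing_rate > 0:
            mask = rng.random((n, k)) < config.missing_rate
            y = np.where(mask, np.nan, y)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(subjects, k),
                    "session_label": np.tile(labels, n),
                    "idp_name": spec.idp_name,
                    "value": y.ravel(),
                }
            )
        )

    sessions = [
        SessionInfo(s.session_label, s.site_name, s.manufacturer, s.scanner_model)
        for s in config.sessions
    ]
    class_map = {s.idp_name: s.class_label for s in config.idp_specs}
    return IDPTable(pd.concat(frames, ignore_index=True), sessions, class_map)


def generate_reference_cohort(n_subjects: int, idp_specs, seed: int = 0) -> IDPTable:
    """Simulate a large single-scanner test-retest cohort (two visits).

    Same variance-component model as the travelling-heads generator but with
    no site offsets or scalings — the reference condition in which all
    between-session disagreement is measurement noise.
    """
    sessions = (
        SiteEffectSpec("visit1", manufacturer=Manufacturer.NONE),
        SiteEffectSpec("visit2", manufacturer=Manufacturer.NONE),
    )
    config = GeneratorConfig(
        n_subjects=n_subjects,
        sessions=sessions,
        idp_specs=tuple(idp_specs),
        missing_rate=0.0,
        seed=seed,
    )
    return generate_travelling_heads(config)


def specs_for_icc(
    n_idps: int,
    icc_true: float,
    class_label: str = "unclassified",
    mu: float = 0.0,
    prefix: str = "idp",
) -> tuple:
    """Phenotype specs whose theoretical consistency ICC equals ``icc_true``.

    Unit total variance: ``sigma_subject = sqrt(icc)``,
    ``sigma_error = sqrt(1 - icc)``.
    """
    if not 0 <= icc_true <= 1:
        raise ConfigurationError("icc_true must lie in [0, 1]")
    ss = float(np.sqrt(icc_true))
    se = float(np.sqrt(1.0 - icc_true))
    return tuple(
        IdpSpec(f"{prefix}{i + 1:04d}", class_label, mu, ss, se) for i in range(n_idps)
    )
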