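"""Registry of the 11-score expanded neuropsychological battery.

Eleven scores come from eight instruments (the HVLT-R contributes three:
total recall, delayed recall and recognition).  Five scores form the
attention/executive domain: SDMT, TMT-A, LNS, lexical (COWAT) fluency and
TMT-B.  Timed trail-making scores are recorded in seconds, so higher raw
values mean worse performance; the ``higher_is_worse`` flag marks them and
drives the sign flip applied during T-scoring.

The raw-score locations/scales and the demographic effects attached to each
entry are *simulation defaults only*: plausible published ranges used by the
synthetic cohort generator so that normative regression has real signal.
Their exact values are irrelevant downstream because regression norming
standardizes every test to the T metric (affine invariance is asserted in
the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from iivd.errors import ValidationError

ATTENTION_EXECUTIVE = "attention_executive"


@dataclass(frozen=True)
class TestSpec:
    """One battery score: identity, domain, orientation and sim defaults.

    ``raw_loc``/``raw_per_t`` place simulated scores on a plausible raw
    scale (raw = loc + raw_per_t * signed T deviation).  ``age_slope_t``,
    ``edu_slope_t`` and ``sex_effect_t`` are demographic effects in T units
    (per year of age, per year of education, male minus female) injected by
    the simulator and removed again by norming.
    """

    name: str
    label: str
    domain: str
    higher_is_worse: bool = False
    covariates: tuple[str, ...] = ("age", "sex", "education")
    raw_loc: float = 50.0
    raw_per_t: float = 1.0
    age_slope_t: float = 0.0
    edu_slope_t: float = 0.0
    sex_effect_t: float = 0.0


@dataclass(frozen=True)
class TestRegistry:
    """Fixed collection of exactly 11 test specs (5 attention/executive)."""

    tests: tuple[TestSpec, ...]

    def __post_init__(self) -> None:
        names = [t.name for t in self.tests]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate test names in registry")
        if len(self.tests) != 11:
            raise ValidationError(
                f"registry must hold exactly 11 tests, got {len(self.tests)}"
            )
        n_ae = sum(t.domain == ATTENTION_EXECUTIVE for t in self.tests)
        if n_ae != 5:
            raise ValidationError(
                f"registry must tag exactly 5 attention/executive tests, got {n_ae}"
            )

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.tests]

    @property
    def attention_executive(self) -> list[str]:
        return [t.name for t in self.tests if t.domain == ATTENTION_EXECUTIVE]

    def __getitem__(self, name: str) -> TestSpec:
        for t in self.tests:
            if t.name == name:
                return t
        raise KeyError(f"no such test in registry: {name!r}")

    def __iter__(self):
        return iter(self.tests)


def default_registry() -> TestRegistry:
    """The standard 11-score battery with simulation defaults."""
    return TestRegistry(
        tests=(
            TestSpec(
                "jlo", "Benton Judgement of Line Orientation", "visuospatial",
                raw_loc=25.9, raw_per_t=0.33,
                age_slope_t=-0.20, edu_slope_t=0.45, sex_effect_t=1.5,
            ),
            TestSpec(
                "hvlt_total", "HVLT-R Total Recall", "memory",
                raw_loc=26.0, raw_per_t=0.45,
                age_slope_t=-0.30, edu_slope_t=0.55, sex_effect_t=-2.0,
            ),
            TestSpec(
                "hvlt_delayed", "HVLT-R Delayed Recall", "memory",
                raw_loc=9.2, raw_per_t=0.25,
                age_slope_t=-0.28, edu_slope_t=0.50, sex_effect_t=-2.0,
            ),
            TestSpec(
                "hvlt_recog", "HVLT-R Recognition Discrimination", "memory",
                raw_loc=11.0, raw_per_t=0.12,
                age_slope_t=-0.15, edu_slope_t=0.30, sex_effect_t=-1.0,
            ),
            TestSpec(
                "lns", "WAIS-IV Letter-Number Sequencing", ATTENTION_EXECUTIVE,
                raw_loc=10.5, raw_per_t=0.26,
                age_slope_t=-0.25, edu_slope_t=0.75, sex_effect_t=0.0,
            ),
            TestSpec(
                "cowat", "COWAT lexical fluency", ATTENTION_EXECUTIVE,
                raw_loc=42.0, raw_per_t=1.10,
                age_slope_t=-0.15, edu_slope_t=0.90, sex_effect_t=-0.5,
            ),
            TestSpec(
                "bnt", "Modified Boston Naming Test", "language",
                raw_loc=28.5, raw_per_t=0.18,
                age_slope_t=-0.10, edu_slope_t=0.40, sex_effect_t=0.5,
            ),
            TestSpec(
                "semantic_fluency", "Modified semantic fluency", "language",
                raw_loc=48.0, raw_per_t=1.10,
                age_slope_t=-0.25, edu_slope_t=0.70, sex_effect_t=-0.5,
            ),
            TestSpec(
                "sdmt", "Symbol Digit Modalities Test (oral)", ATTENTION_EXECUTIVE,
                raw_loc=45.0, raw_per_t=1.00,
                age_slope_t=-0.45, edu_slope_t=0.80, sex_effect_t=-1.0,
            ),
            TestSpec(
                "tmt_a", "Trail Making Test Part A (seconds)", ATTENTION_EXECUTIVE,
                higher_is_worse=True,
                raw_loc=35.0, raw_per_t=1.20,
                age_slope_t=-0.35, edu_slope_t=0.45, sex_effect_t=0.0,
            ),
            TestSpec(
                "tmt_b", "Trail Making Test Part B (seconds)", ATTENTION_EXECUTIVE,
                higher_is_worse=True,
                raw_loc=85.0, raw_per_t=3.80,
                age_slope_t=-0.40, edu_slope_t=0.70, sex_effect_t=0.0,
            ),
        )
    )
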