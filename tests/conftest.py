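import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def template_ls():
    from phenoface.landmarks import template_landmarks

    return template_landmarks()


@pytest.fixture(scope="session")
def template_image(template_ls):
    from phenoface.synthetic import render_face

    return render_face(template_ls.points)


@pytest.fixture(scope="session")
def small_rendered_cohort():
    """A small rendered cohort with the default planted effects (one stratum)."""
    from phenoface.synthetic import SyntheticCohortConfig, generate_cohort

    cfg = SyntheticCohortConfig(
        group_sizes={("NS", "Caucasian"): 6, ("WBS", "Caucasian"): 6},
        seed=11,
    )
    return generate_cohort(cfg)
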