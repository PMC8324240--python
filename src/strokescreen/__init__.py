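"""strokescreen: sex-stratified stroke-risk prediction and ensemble screening.

A testable re-implementation of a cohort risk-screening workflow: synthetic
cohorts with known ground-truth hazards, Cox and binary risk models behind a
single absolute-risk contract, decile calibration and discrimination
metrics with bootstrap intervals, and a decision-tree arbiter that resolves
disagreements between a Cox model and a gradient-boosted-tree model when
screening individuals at >10% nine-year stroke risk.
"""

from .config import GeneratorConfig, RunConfig

__version__ = "0.1.0"


def __getattr__(name):  # lazy re-exports keep `import strokescreen` light
    from importlib import import_module

    locations = {
        "generate_cohort": "cohort",
        "summarize_cohort": "cohort",
        "true_risk": "cohort",
        "split_cohort": "prep",
        "make_survival_dataset": "prep",
        "make_binary_dataset": "prep",
        "fit_cox": "models",
        "fit_binary": "models",
        "auroc": "metrics",
        "hosmer_lemeshow": "metrics",
        "nam_dagostino": "metrics",
        "bootstrap_ci": "metrics",
        "run_pipeline": "pipeline",
    }
    if name in locations:
        return getattr(import_module(f".{locations[name]}", __name__), name)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")


__all__ = [
    "GeneratorConfig",
    "RunConfig",
    "generate_cohort",
    "summarize_cohort",
    "true_risk",
    "split_cohort",
    "fit_cox",
    "fit_binary",
    "auroc",
    "hosmer_lemeshow",
    "nam_dagostino",
    "bootstrap_ci",
    "run_pipeline",
    "__version__",
]
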