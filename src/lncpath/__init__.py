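"""lncpath: pathway-associated lncRNA discovery, subtyping and risk modeling.

Pipeline stages: purity-adjusted association ranking, preranked enrichment
with the TES screen, bootstrap consensus subtyping, signature scoring, and a
Cox/Lasso/stepwise-AIC risk model; plus a synthetic cohort generator with
recorded ground truth.
"""

from importlib import resources

__version__ = "0.1.0"


def published_model_path():
    """Path to the shipped six-term risk-model JSON fixture."""
    return resources.files("lncpath.data") / "published_model.json"


def data_path(name: str):
    """Path to a shipped data fixture (model JSON or signature GMT)."""
    return resources.files("lncpath.data") / name
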