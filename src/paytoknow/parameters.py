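"""Subject-level parameters of the pay-to-know value model.

A subject is described by a money weight ``alpha``, valence-specific
"unknown aversion" weights ``beta_pos``/``beta_neg`` (the subjective cost of
*not* knowing an evaluation, bounded in [-1, 1]), a softmax inverse
temperature ``gamma`` and a lapse rate ``epsilon``.  Optional terms cover the
model variants: a per-trial ``discount`` on the value of knowing and a
``loss_lambda`` loss-aversion multiplier on negative payoffs.  ``bdi`` carries
the Beck Depression Inventory score used as an individual-difference
covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

__all__ = ["PARAM_BOUNDS", "SubjectParameters"]

# Hard bounds.  The beta range is substantive (maximal aversion to not-knowing
# at +1, to knowing at -1); epsilon in [0, 0.5] is forced by the (1 - 2e)
# lapse form; the rest are wide enough to be non-binding at realistic values.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.0, 10.0),
    "beta_pos": (-1.0, 1.0),
    "beta_neg": (-1.0, 1.0),
    "gamma": (1e-3, 30.0),
    "epsilon": (0.0, 0.5),
    "discount": (1e-3, 1.0),
    "loss_lambda": (1.0, 5.0),
}


@dataclass
class SubjectParameters:
    """Generative or fitted parameters for one subject (one session).

    For the shared-aversion model ``beta_pos == beta_neg``; the convenience
    property :attr:`beta` returns the common value in that case.
    """

    alpha: float = 1.0
    beta_pos: float = 0.0
    beta_neg: float = 0.0
    gamma: float = 3.0
    epsilon: float = 0.0
    discount: Optional[float] = None
    loss_lambda: Optional[float] = None
    bdi: Optional[int] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("alpha", "beta_pos", "beta_neg", "gamma", "epsilon"):
            lo, hi = PARAM_BOUNDS[name]
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside bounds [{lo}, {hi}]")
        for name in ("discount", "loss_lambda"):
            v = getattr(self, name)
            if v is not None:
                lo, hi = PARAM_BOUNDS[name]
                if not (lo <= v <= hi):
                    raise ValueError(f"{name}={v} outside bounds [{lo}, {hi}]")
        if self.bdi is not None and self.bdi < 0:
            raise ValueError(f"bdi={self.bdi} must be non-negative")

    @property
    def beta(self) -> float:
        """Shared unknown-aversion weight; defined when both valences agree."""
        if self.beta_pos != self.beta_neg:
            raise ValueError(
                "beta is only defined when beta_pos == beta_neg "
                f"(got {self.beta_pos} vs {self.beta_neg})"
            )
        return self.beta_pos

    def beta_for(self, valence: str) -> float:
        """Unknown-aversion weight for a trait valence ('positive'/'negative')."""
        if valence == "positive":
            return self.beta_pos
        if valence == "negative":
            return self.beta_neg
        raise ValueError(f"unknown valence {valence!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectParameters":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})
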