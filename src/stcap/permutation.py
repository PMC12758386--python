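"""Shared permutation-test result container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PermutationResult:
    """Empirical permutation test outcome with add-one correction.

    ``p = (1 + #{null as-or-more-extreme}) / (1 + n_perm)`` so p is never 0.
    ``direction`` documents what counts as more extreme.
    """

    observed: float
    null: np.ndarray
    direction: str
    extra: dict = field(default_factory=dict)

    @property
    def n_perm(self) -> int:
        return int(self.null.size)

    @property
    def p(self) -> float:
        if self.direction == "less":
            more_extreme = int((self.null <= self.observed).sum())
        elif self.direction == "greater":
            more_extreme = int((self.null >= self.observed).sum())
        elif self.direction == "two-sided":
            more_extreme = int(
                (np.abs(self.null) >= abs(self.observed)).sum())
        else:
            raise ValueError(f"unknown direction {self.direction!r}")
        return (1 + more_extreme) / (1 + self.n_perm)

    def summary(self) -> dict:
        return {
            "observed": float(self.observed),
            "p": float(self.p),
            "direction": self.direction,
            "n_perm": self.n_perm,
            "null_mean": float(self.null.mean()) if self.n_perm else float("nan"),
            "null_sd": float(self.null.std()) if self.n_perm else float("nan"),
            **self.extra,
        }
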