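"""Adam optimizer (NumPy).

Used for both pattern learning and network training: first/second-moment
coefficients default to 0.9 / 0.999 with learning rate 2e-4, the schedule
the reconstruction models are trained with.
"""

from __future__ import annotations

import numpy as np

__all__ = ["AdamOptimizer"]


class AdamOptimizer:
    def __init__(self, lr: float = 2e-4, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = float(eps)

    def init(self, param: np.ndarray) -> dict:
        return {
            "m": np.zeros_like(np.asarray(param, dtype=np.float64)),
            "v": np.zeros_like(np.asarray(param, dtype=np.float64)),
            "t": 0,
        }

    def step(self, state: dict, param: np.ndarray, grad: np.ndarray) -> np.ndarray:
        """One bias-corrected Adam update; mutates ``state``, returns new param."""
        state["t"] += 1
        t = state["t"]
        state["m"] = self.beta1 * state["m"] + (1.0 - self.beta1) * grad
        state["v"] = self.beta2 * state["v"] + (1.0 - self.beta2) * grad * grad
        m_hat = state["m"] / (1.0 - self.beta1**t)
        v_hat = state["v"] / (1.0 - self.beta2**t)
        return param - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
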