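"""Training dynamics: ramp-up loss weights, EMA teacher, poly learning rate.

The unsupervised loss weights follow a Gaussian ramp-up so the model
focuses on labeled images early and shifts to unlabeled images as
training stabilises:

    lambda1(t) = w_base * exp(-5 * (1 - t / tmax)^2),   w_base = 0.01
    lambda2(t) = u * lambda1(t),                        u = 15

where the ramp step ``t = floor(iteration / ramp_every)`` advances every
``ramp_every`` iterations (150 at full scale) up to
``tmax = total_iters / ramp_every``.

The teacher's parameters are the exponential moving average of the
student's, ``theta_t = decay * theta_{t-1} + (1 - decay) * theta_s``,
applied once per iteration after the optimizer step; the teacher is never
touched by the optimizer.  The learning rate follows the poly policy
``lr = base * (1 - iteration / total_iters)^0.9``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import nn


def lambda1(t: float, tmax: float, base_weight: float = 0.01) -> float:
    """Gaussian ramp-up consistency weight; saturates at ``base_weight``."""
    if tmax <= 0:
        raise ValueError("tmax must be positive")
    t = min(max(t, 0.0), tmax)  # saturate past the horizon
    return base_weight * math.exp(-5.0 * (1.0 - t / tmax) ** 2)


def lambda2(t: float, tmax: float, u: float = 15.0, base_weight: float = 0.01) -> float:
    """Co-training weight: a fixed multiple ``u`` of ``lambda1``."""
    if u < 0:
        raise ValueError("scaling factor u must be nonnegative")
    return u * lambda1(t, tmax, base_weight)


def ramp_step(iteration: int, ramp_every: int = 150) -> int:
    """Ramp step t advances once per ``ramp_every`` iterations."""
    if iteration < 0:
        raise ValueError("iteration must be nonnegative")
    return iteration // ramp_every


def poly_lr(iteration: int, total_iters: int, base_lr: float = 0.01,
            power: float = 0.9) -> float:
    """Poly learning-rate decay, reaching 0 at ``total_iters``."""
    frac = min(max(iteration / total_iters, 0.0), 1.0)
    return base_lr * (1.0 - frac) ** power


@dataclass
class RampSchedule:
    """Weight schedule state for one training run."""

    base_weight: float = 0.01
    u: float = 15.0
    ramp_every: int = 150
    total_iters: int = 30_000

    @property
    def tmax(self) -> float:
        return self.total_iters / self.ramp_every

    def step_of(self, iteration: int) -> int:
        return ramp_step(iteration, self.ramp_every)

    def weights_at(self, iteration: int) -> tuple[float, float]:
        t = self.step_of(iteration)
        l1 = lambda1(t, self.tmax, self.base_weight)
        return l1, self.u * l1


class StateError(ValueError):
    pass


@dataclass
class TeacherState:
    """EMA copy of the student; parameter names and shapes mirror it."""

    model: nn.Module
    decay: float = 0.99
    update_count: int = 0
    warmup: bool = False  # min(decay, 1 - 1/(count+1)) ramped decay, off by default

    def effective_decay(self) -> float:
        if self.warmup:
            return min(self.decay, 1.0 - 1.0 / (self.update_count + 1))
        return self.decay


def ema_update(state: TeacherState, student: nn.Module) -> TeacherState:
    """In-place EMA of teacher parameters (and normalisation buffers)."""
    t_params = dict(state.model.named_parameters())
    s_params = dict(student.named_parameters())
    bad = sorted(set(t_params) ^ set(s_params))
    bad += sorted(k for k in t_params if k in s_params
                  and t_params[k].data.shape != s_params[k].data.shape)
    if bad:
        raise StateError(f"teacher/student parameter mismatch: {bad}")
    lam = state.effective_decay()
    for name, tp in t_params.items():
        tp.data = lam * tp.data + (1.0 - lam) * s_params[name].data
    t_bufs = dict(state.model.named_buffers())
    s_bufs = dict(student.named_buffers())
    for (mod_name, mod) in _buffered_modules(state.model):
        for bname in list(mod._buffers):
            full = mod_name + bname
            if full in s_bufs:
                mod._set_buffer(bname, lam * t_bufs[full] + (1.0 - lam) * s_bufs[full])
    state.update_count += 1
    return state


def _buffered_modules(root: nn.Module, prefix: str = ""):
    if root._buffers:
        yield prefix, root
    for name, m in root._modules.items():
        yield from _buffered_modules(m, prefix + name + ".")


def make_teacher(student: nn.Module, factory, decay: float = 0.99) -> TeacherState:
    """Build a teacher as a parameter copy of the student at iteration 0."""
    teacher = factory()
    teacher.load_state_dict(student.state_dict())
    for p in teacher.parameters():
        p.requires_grad = False
    return TeacherState(model=teacher, decay=decay)
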