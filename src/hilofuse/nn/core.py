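"""Minimal NumPy neural-network core with explicit reverse-mode gradients.

Every layer is a :class:`Module` with ``forward``/``backward`` methods; the
backward pass consumes the gradient of the loss w.r.t. the layer output and
returns the gradient w.r.t. its input while accumulating parameter gradients
in place.  float32 throughout; caches needed for the backward pass are only
stored while the module is in training mode, so inference on large volumes
stays memory-light.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Parameter:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    @property
    def shape(self):
        return self.value.shape


class Module:
    def __init__(self):
        self.training = True

    # -- parameter / buffer discovery -------------------------------------
    def named_parameters(self, prefix=""):
        for key, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix + key + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{key}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix=""):
        buf = getattr(self, "_buffers", None)
        if buf:
            for key, val in buf.items():
                yield prefix + key, val
        for key, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.named_buffers(prefix + key + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{key}.{i}.")

    def set_buffer(self, name, value):
        if not hasattr(self, "_buffers"):
            self._buffers = {}
        self._buffers[name] = value

    # -- mode handling -----------------------------------------------------
    def train(self, mode: bool = True):
        self.training = mode
        for key, val in vars(self).items():
            if isinstance(val, Module):
                val.train(mode)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- forward/backward contract ----------------------------------------
    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    # -- (de)serialization -------------------------------------------------
    def state_dict(self):
        state = {f"param.{k}": p.value for k, p in self.named_parameters()}
        state.update({f"buffer.{k}": b for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state):
        for k, p in self.named_parameters():
            p.value[...] = state[f"param.{k}"]
        buffers = dict(self.named_buffers())
        for k in buffers:
            buffers[k][...] = state[f"buffer.{k}"]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m.forward(x)
        return x

    def backward(self, grad):
        for m in reversed(self.mods):
            grad = m.backward(grad)
        return grad
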