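from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def shape(self):
        return self.value.shape

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: a layer with `forward(x, train)` and `backward(dy)`.

    `backward` must be called after `forward` (layers cache what they
    need) and returns the gradient with respect to the forward input.
    """

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for attr in vars(self).values():
            for p in _collect(attr):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)

    # -- checkpointing ------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of all parameters and buffers."""
        out: dict[str, np.ndarray] = {}
        _state(self, "", out)
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        missing = set(own) ^ set(arrays)
        if missing:
            raise KeyError(f"state mismatch on keys: {sorted(missing)}")
        for k, v in own.items():
            v[...] = arrays[k]


def _collect(obj):
    if isinstance(obj, Parameter):
        yield obj
    elif isinstance(obj, Module):
        yield from obj.parameters()
    elif isinstance(obj, (list, tuple)):
        for item in obj:
            yield from _collect(item)


def _state(obj, prefix: str, out: dict[str, np.ndarray]) -> None:
    if isinstance(obj, Module):
        for name, attr in vars(obj).items():
            if name.startswith("_"):
                continue  # private forward caches are not model state
            _state(attr, f"{prefix}{name}.", out)
    elif isinstance(obj, Parameter):
        out[prefix[:-1]] = obj.value
    elif isinstance(obj, np.ndarray):
        # buffers (e.g. batchnorm running stats)
        out[prefix[:-1]] = obj
    elif isinstance(obj, (list, tuple)):
        for i, item in enumerate(obj):
            _state(item, f"{prefix}{i}.", out)
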