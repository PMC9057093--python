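"""Module/Parameter machinery shared by all layers."""

from __future__ import annotations

from typing import Iterator

import numpy as np


class Parameter:
    """A trainable array with an accumulated gradient."""

    def __init__(self, data: np.ndarray, trainable: bool = True):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.trainable = trainable

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g


class Module:
    """Base class: child modules and parameters auto-register on attribute set."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield (f"{prefix}{name}", p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    # -- modes -----------------------------------------------------------
    def train(self) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", True)
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", False)
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- state -----------------------------------------------------------
    def _buffers(self) -> dict[str, np.ndarray]:
        """Non-trainable per-module state (e.g. batch-norm running stats)."""
        return {}

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        object.__setattr__(self, name, value)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {f"{prefix}{k}": p.data.copy() for k, p in self._params.items()}
        for k, v in self._buffers().items():
            out[f"{prefix}{k}"] = np.asarray(v).copy()
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix=f"{prefix}{name}."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, p in self._params.items():
            key = f"{prefix}{k}"
            if key not in state:
                raise KeyError(f"missing parameter {key!r} in state dict")
            if state[key].shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {key!r}: checkpoint {state[key].shape}, "
                    f"model {p.data.shape}"
                )
            p.data = state[key].astype(p.data.dtype, copy=True)
        for k in self._buffers():
            key = f"{prefix}{k}"
            if key in state:
                self._set_buffer(k, state[key].copy())
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix=f"{prefix}{name}.")

    def astype(self, dtype) -> "Module":
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for m in self.modules():
            for k, v in m._buffers().items():
                m._set_buffer(k, np.asarray(v).astype(dtype))
        return self

    # -- interface -------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class ModuleList(Module):
    def __init__(self, mods: list[Module] | None = None):
        super().__init__()
        self._items: list[Module] = []
        for m in mods or []:
            self.append(m)

    def append(self, m: Module) -> None:
        self._modules[str(len(self._items))] = m
        self._items.append(m)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.items = ModuleList(list(mods))

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self.items:
            x = m(x)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for m in reversed(list(self.items)):
            gout = m.backward(gout)
        return gout
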