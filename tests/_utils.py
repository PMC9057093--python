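"""Shared test helpers."""

import numpy as np


def _scalar(out, loss):
    return loss(out[0] if isinstance(out, tuple) else out)


def fd_gradcheck(module, x, n_param_samples=24, h=1e-6, seed=0,
                 loss=lambda out: float(np.sum(np.sin(out)))):
    """Central finite-difference check of parameter and input gradients.

    The module must hold float64 parameters.  Uses sum(sin(out)) as a
    generic scalar loss; for modules returning (out, mask) tuples the
    gradient flows through the combined output only.  Returns the maximum
    relative error over all sampled coordinates.
    """
    rng = np.random.default_rng(seed)
    state0 = module.state_dict()
    module.load_state_dict(state0)
    out = module.forward(x)
    raw = out[0] if isinstance(out, tuple) else out
    module.zero_grad()
    gin = module.backward(np.cos(raw))
    params = list(module.named_parameters())
    errs = []
    per_param = max(1, n_param_samples // max(len(params), 1))
    for _, p in params:
        for _ in range(per_param):
            idx = tuple(int(rng.integers(0, s)) for s in p.data.shape)
            orig = float(p.data[idx])
            module.load_state_dict(state0)
            p.data[idx] = orig + h
            lp = _scalar(module.forward(x), loss)
            module.load_state_dict(state0)
            p.data[idx] = orig - h
            lm = _scalar(module.forward(x), loss)
            module.load_state_dict(state0)
            fd = (lp - lm) / (2 * h)
            errs.append(abs(fd - float(p.grad[idx])) / max(1.0, abs(fd)))
    for _ in range(6):
        idx = tuple(int(rng.integers(0, s)) for s in x.shape)
        xp = x.copy(); xp[idx] += h
        lp = _scalar(module.forward(xp), loss)
        xm = x.copy(); xm[idx] -= h
        lm = _scalar(module.forward(xm), loss)
        fd = (lp - lm) / (2 * h)
        errs.append(abs(fd - float(gin[idx])) / max(1.0, abs(fd)))
    return max(errs)


def randomize_params(module, rng, scale=0.3):
    for p in module.parameters():
        p.data = rng.normal(scale=scale, size=p.data.shape)
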