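import numpy as np

from predrigid.core import TargetRow


def random_rows(seed: int, n: int, d: int, weights=None, values=True):
    """Seeded random gradient rows for oracle comparisons."""
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((n, d))
    lam = np.ones(n) if weights is None else weights
    y = rng.standard_normal(n) if values else np.zeros(n)
    return [
        TargetRow(grad_w=G[i], weight=float(lam[i]), value=float(y[i]))
        for i in range(n)
    ]
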