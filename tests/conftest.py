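import numpy as np
import pytest
from hypothesis import settings

from pktopo.config import RunConfig

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_cfg() -> RunConfig:
    """Coarse desk-scale enumeration profile for fast exhaustive runs."""
    return RunConfig(n_axes=14, n_alphas=4, grid_coarsen=4.0,
                     max_nodes=2000)


@pytest.fixture(scope="session")
def micro_cfg() -> RunConfig:
    """Very coarse profile for CLI smoke runs."""
    return RunConfig(n_axes=8, n_alphas=3, grid_coarsen=5.0, max_nodes=2000)


def brute_force_viable(n_nt, start, prev, end, context, cfg) -> bool:
    """Unpruned depth-first enumeration over the full direction set.

    Independent oracle for loop-closure viability: same chain contract as
    the engine (anchors are bonded termini, immediate predecessor bonded),
    but no reach pruning, no candidate ordering, no node budget.
    """
    from pktopo.sampler import extension_directions

    b = cfg.bond_length
    close_r = b + cfg.closure_tol
    ctx = (np.empty((0, 3)) if context is None
           else np.asarray(context, dtype=float).reshape(-1, 3))
    if n_nt == 0:
        return bool(np.linalg.norm(np.asarray(start) - np.asarray(end))
                    <= close_r)
    hit = []

    def rec(chain, cur, prev_pt):
        if hit:
            return
        if len(chain) == 2 * n_nt:
            if np.linalg.norm(cur - end) <= close_r:
                hit.append(1)
            return
        for d in extension_directions(cur - prev_pt, cfg):
            pt = cur + b * d
            if len(ctx) and np.min(
                    np.linalg.norm(ctx - pt, axis=1)) < cfg.ev_cutoff:
                continue
            if any(np.linalg.norm(q - pt) < cfg.ev_cutoff
                   for q in chain[:-1]):
                continue
            chain.append(pt)
            rec(chain, pt, cur)
            chain.pop()

    rec([], np.asarray(start, dtype=float), np.asarray(prev, dtype=float))
    return bool(hit)
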