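"""Helpers to build datasets drawn from the mixture model itself."""

import numpy as np

from bhts.bhts_core import MCMCState, sample_readouts_from_state
from bhts.plate_io import Plate, ScreenDataset, WellRole


def template_dataset(n_plates, n_rows=8, n_cols=10):
    plates = []
    for m in range(n_plates):
        roles = np.empty((n_rows, n_cols), dtype=object)
        roles[:, :] = WellRole.COMPOUND
        plates.append(Plate(f"P{m + 1}", np.zeros((n_rows, n_cols)), roles))
    return ScreenDataset(plates=plates)


def two_atom_state(n_plates, pi, active_means=(0.30, 0.32),
                   inactive_means=(0.10, 0.12), var=4e-4):
    """H=K=2 state with well-separated fixed atoms and equal local weights."""
    return MCMCState(
        pi=pi,
        b=np.zeros(1, dtype=int),
        local_labels=np.zeros(1, dtype=int),
        local_to_global=np.tile(np.arange(2), (n_plates, 2, 1)),
        local_sticks=np.tile(np.array([0.5, 1.0]), (n_plates, 2, 1)),
        global_sticks=np.tile(np.array([0.5, 1.0]), (2, 1)),
        atom_means=np.array([list(inactive_means), list(active_means)]),
        atom_vars=np.full((2, 2), var),
        alpha=np.ones(2),
        tau=np.ones(2),
    )


def model_generated_dataset(pi, seed, n_plates=10, n_rows=8, n_cols=10):
    """Dataset drawn from a fixed well-separated H=K=2 configuration."""
    ds = template_dataset(n_plates, n_rows, n_cols)
    state = two_atom_state(n_plates, pi)
    rng = np.random.default_rng(seed)
    z, b = sample_readouts_from_state(state, ds, rng)
    per = n_rows * n_cols
    plates = []
    for m, p in enumerate(ds.plates):
        vals = z[m * per : (m + 1) * per].reshape(n_rows, n_cols)
        plates.append(Plate(p.plate_id, vals, p.roles))
    return ScreenDataset(plates=plates, truth=b.astype(bool))
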