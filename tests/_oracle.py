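"""Independent oracles: exhaustive-enumeration smoothing for tiny models.

Enumerates every joint state trajectory of a generative model under a fixed
policy, weights it by prior x transition x likelihood probability, and
marginalizes.  Deliberately brute force and independent of the engine's
message-passing code path.
"""

from __future__ import annotations

import itertools

import numpy as np

from pfcsim.model import FactorSpec, GenerativeModel, ModalitySpec


def enumeration_smoother(
    model: GenerativeModel, obs_idx: list[list[int]], pi: int = 0
) -> tuple[list[np.ndarray], float]:
    """Exact per-factor smoothed marginals and evidence, by enumeration.

    ``obs_idx[tau-1][g]`` is the observed outcome index for modality ``g``
    at time ``tau``; trajectories are weighted under policy ``pi``.
    Returns (marginals[n][tau] arrays, P(observations | policy)).
    """
    T = model.T
    dims = model.state_dims
    N = len(dims)
    cf = model.controlled_factor
    marg = [np.zeros((T, d)) for d in dims]
    evidence = 0.0
    per_factor_paths = [
        list(itertools.product(range(d), repeat=T)) for d in dims
    ]
    for joint_path in itertools.product(*per_factor_paths):
        # joint_path[n][tau-1] is factor n's level at time tau
        p = 1.0
        for n in range(N):
            p *= model.D[n][joint_path[n][0]]
            for tau in range(2, T + 1):
                u = model.policies[pi, tau - 2] if n == cf else 0
                p *= model.B[n][u][joint_path[n][tau - 1], joint_path[n][tau - 2]]
        if p == 0.0:
            continue
        for tau in range(1, T + 1):
            state = tuple(joint_path[n][tau - 1] for n in range(N))
            for g in range(len(model.modalities)):
                p *= model.A[g][tau - 1][(obs_idx[tau - 1][g],) + state]
        if p == 0.0:
            continue
        evidence += p
        for n in range(N):
            for tau in range(T):
                marg[n][tau, joint_path[n][tau]] += p
    if evidence > 0:
        for n in range(N):
            marg[n] /= marg[n].sum(axis=1, keepdims=True)
    return marg, evidence


def random_small_model(
    rng: np.random.Generator,
    n_factors: int = 1,
    max_levels: int = 3,
    T: int = 3,
    deterministic: bool = False,
) -> GenerativeModel:
    """A random tiny model (single policy, single modality per factor pair)."""
    dims = [int(rng.integers(2, max_levels + 1)) for _ in range(n_factors)]
    n_out = int(rng.integers(2, max_levels + 1))
    factors = [
        FactorSpec(f"f{n}", tuple(f"f{n}l{i}" for i in range(d)))
        for n, d in enumerate(dims)
    ]
    modality = ModalitySpec("o", tuple(f"o{i}" for i in range(n_out)), f"o{n_out - 1}")
    shape = (T, n_out) + tuple(dims)
    if deterministic:
        A = np.zeros(shape)
        for t in range(T):
            for state in itertools.product(*(range(d) for d in dims)):
                A[(t, int(rng.integers(n_out))) + state] = 1.0
        B = []
        for d in dims:
            Bn = np.zeros((1, d, d))
            for j in range(d):
                Bn[0, int(rng.integers(d)), j] = 1.0
            B.append(Bn)
        D = []
        for d in dims:
            Dn = np.zeros(d)
            Dn[int(rng.integers(d))] = 1.0
            D.append(Dn)
    else:
        n_states = int(np.prod(dims))
        A = (
            rng.dirichlet(np.ones(n_out), size=(T, n_states))
            .transpose(0, 2, 1)
            .reshape(shape)
        )
        B = [
            rng.dirichlet(np.ones(d), size=(1, d)).transpose(0, 2, 1) for d in dims
        ]
        D = [rng.dirichlet(np.ones(d)) for d in dims]
    C = [np.zeros((T, n_out))]
    return GenerativeModel(
        factors=factors,
        modalities=[modality],
        A=[A],
        B=B,
        C=C,
        D=D,
        policies=np.zeros((1, T - 1), dtype=np.intp),
        T=T,
        controlled_factor=0,
    )


def sample_observations(
    model: GenerativeModel, rng: np.random.Generator
) -> list[list[int]]:
    """Draw a state trajectory and outcomes from the model's own process."""
    N = len(model.factors)
    state = [int(rng.choice(len(model.D[n]), p=model.D[n])) for n in range(N)]
    obs = []
    for tau in range(1, model.T + 1):
        row = []
        for g in range(len(model.modalities)):
            probs = model.A[g][tau - 1][(slice(None),) + tuple(state)]
            row.append(int(rng.choice(len(probs), p=probs)))
        obs.append(row)
        if tau < model.T:
            state = [
                int(rng.choice(model.B[n].shape[1], p=model.B[n][0][:, state[n]]))
                for n in range(N)
            ]
    return obs


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p || q) with the 0 ln 0 = 0 convention."""
    mask = p > 0
    return float(np.sum(p[mask] * (np.log(p[mask]) - np.log(np.maximum(q[mask], 1e-300)))))
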