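import numpy as np
import pytest

from nstrat.markers import MarkerRegistry, ProfileModel
from nstrat.strategies import RuleSet


@pytest.fixture(scope="session")
def registry() -> MarkerRegistry:
    """Calibrated synthetic registry shared across the suite (expensive)."""
    return MarkerRegistry.synthetic(seed=7)


@pytest.fixture(scope="session")
def uncalibrated_registry() -> MarkerRegistry:
    return MarkerRegistry.synthetic(seed=7, calibrate=False)


@pytest.fixture
def rules() -> RuleSet:
    return RuleSet()


def random_profile(rng: np.random.Generator, M: int) -> ProfileModel:
    """A valid random profile with normalized emissions and transitions."""
    def simplex(shape):
        x = rng.gamma(1.0, size=shape)
        return x / x.sum(axis=-1, keepdims=True)

    n_t = max(M - 1, 0)
    tm = simplex((n_t, 3)) if n_t else np.zeros((0, 3))
    ti = simplex((n_t, 2)) if n_t else np.zeros((0, 2))
    td = simplex((n_t, 2)) if n_t else np.zeros((0, 2))
    return ProfileModel(
        marker_id="rand",
        match_emissions=simplex((M, 20)),
        insert_emissions=simplex(20),
        t_mm=tm[:, 0], t_mi=tm[:, 1], t_md=tm[:, 2],
        t_im=ti[:, 0], t_ii=ti[:, 1],
        t_dm=td[:, 0], t_dd=td[:, 1],
        background=simplex(20),
    )


def enumerate_forward_score(profile: ProfileModel, sequence: str) -> float:
    """Independent oracle: exhaustively enumerate all local alignment paths.

    Entry at any match state with mass 1/M at any start residue, exit after
    any match emission; delete states consume no residues and cannot end a
    path.  Returns the log2 odds of the summed path mass.
    """
    from functools import lru_cache

    from nstrat.markers import AA_INDEX

    x = [AA_INDEX[c] for c in sequence]
    L, M = len(x), profile.n_match
    em, ins, bg = profile.match_emissions, profile.insert_emissions, profile.background
    mm, mi, md = profile.t_mm, profile.t_mi, profile.t_md
    im, ii = profile.t_im, profile.t_ii
    dm, dd = profile.t_dm, profile.t_dd

    @lru_cache(maxsize=None)
    def from_match(k: int, i: int) -> float:
        if i >= L:
            return 0.0
        odds = em[k][x[i]] / bg[x[i]]
        total = odds  # exit immediately after this match emission
        if k + 1 < M:
            total += odds * mm[k] * from_match(k + 1, i + 1)
            total += odds * mi[k] * from_insert(k, i + 1)
            total += odds * md[k] * from_delete(k + 1, i + 1)
        return total

    @lru_cache(maxsize=None)
    def from_insert(k: int, i: int) -> float:
        if i >= L:
            return 0.0
        odds = ins[x[i]] / bg[x[i]]
        return odds * (ii[k] * from_insert(k, i + 1) + im[k] * from_match(k + 1, i + 1))

    @lru_cache(maxsize=None)
    def from_delete(k: int, i: int) -> float:
        # Paths may not end in a delete state.
        if i >= L or k >= M - 1:
            return 0.0
        return dm[k] * from_match(k + 1, i) + dd[k] * from_delete(k + 1, i)

    total = sum(
        from_match(k, i) / M for i in range(L) for k in range(M)
    )
    return float(np.log2(total)) if total > 0 else float("-inf")
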