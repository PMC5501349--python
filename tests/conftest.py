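"""Shared fixtures and the exhaustive enumeration oracle.

The oracle enumerates every site-state assignment of a (small) tail by
brute force — independent of the composition-first search-space
construction it is used to check.
"""
from __future__ import annotations

import itertools

import pytest

from middledown.model import (
    MOD_KINDS,
    Modification,
    Proteoform,
    TailSequence,
    proteoform_mass,
)
from middledown.search import SearchConfig


@pytest.fixture
def h3_tail():
    from middledown.model import H3_TAIL

    return H3_TAIL


@pytest.fixture
def h3_config():
    from middledown.model import H3_MODIFIABLE_SITES, LabelScheme

    return SearchConfig(
        modifiable_sites=H3_MODIFIABLE_SITES,
        scheme=LabelScheme(sequence_channel_enabled=False),
    )


@pytest.fixture
def toy_tail():
    return TailSequence(name="toy", residues="ARTK")


@pytest.fixture
def two_k_tail():
    return TailSequence(name="twoK", residues="KGGK")


def site_state_space(cfg: SearchConfig, tail: TailSequence):
    """Per-site lists of possible states: None or a Modification."""
    space = []
    for site, residue, kinds in cfg.site_states(tail):
        states: list[Modification | None] = [None]
        for kind in kinds:
            k = MOD_KINDS[kind]
            hs = range(k + 1) if cfg.scheme.methyl_channel_enabled else (0,)
            for h in hs:
                if h <= k:
                    states.append(Modification(site, residue, kind, h))
        space.append(states)
    return space


def brute_force_candidates(
    precursor_mass: float, cfg: SearchConfig, tail: TailSequence
) -> set[tuple[str, str]]:
    """Exhaustive (notation, channel) set within the precursor window."""
    out: set[tuple[str, str]] = set()
    space = site_state_space(cfg, tail)
    for channel in cfg.channels():
        for combo in itertools.product(*space):
            mods = tuple(m for m in combo if m is not None)
            if len(mods) > cfg.max_mods:
                continue
            p = Proteoform(tail=tail, mods=mods, channel=channel)
            if abs(proteoform_mass(p, cfg.scheme) - precursor_mass) <= cfg.precursor_tol:
                out.add((p.notation, p.channel))
    return out


def all_proteoforms(cfg: SearchConfig, tail: TailSequence, channel: str = "light"):
    """Every proteoform of a small tail under the config's rules."""
    space = site_state_space(cfg, tail)
    for combo in itertools.product(*space):
        mods = tuple(m for m in combo if m is not None)
        if len(mods) > cfg.max_mods:
            continue
        yield Proteoform(tail=tail, mods=mods, channel=channel)
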