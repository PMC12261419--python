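"""The packaged marker-profile collection.

The profiles are synthetic stand-ins for curated enzyme HMMs: each is
built at load time from a consensus peptide listed in
``data/marker_profiles.tsv`` (deterministic match emissions, uniform
background, 20-bit gathering cutoff).  The peptides use an alternating
two-letter design chosen so that any two profiles share at most one
alignable match position, which bounds cross-profile scores at a single
match emission (~4.3 bits) and makes planted/decoy score margins exact.
Swap in a real curated collection by pointing the pipeline at any
HMMER3 ASCII file.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from .fixtures import make_toy_hmm
from .hmmscan import ProfileHMM

__all__ = ["marker_inventory", "default_profiles"]


def marker_inventory() -> list[tuple[str, str, float]]:
    """(profile_name, consensus peptide, cutoff bits) for every packaged marker."""
    ref = resources.files("taxocycle.data").joinpath("marker_profiles.tsv")
    rows: list[tuple[str, str, float]] = []
    for line in ref.read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("profile_name"):
            continue
        name, consensus, cutoff = line.split("\t")
        rows.append((name, consensus, float(cutoff)))
    return rows


@lru_cache(maxsize=1)
def _profiles() -> tuple[ProfileHMM, ...]:
    return tuple(
        make_toy_hmm(consensus, sharpness=1.0, name=name, cutoff_bits=cutoff)
        for name, consensus, cutoff in marker_inventory()
    )


def default_profiles() -> list[ProfileHMM]:
    return list(_profiles())
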