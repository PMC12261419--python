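"""Per-sample occurrence and abundance-weighted function profiles.

Occurrence of a function is the number of community members possessing
it divided by the number of members; relative abundance is the summed
abundance of possessing members divided by the summed abundance of all
members in the sample.  Members are the *resolved* observations with
strictly positive abundance in the sample; unresolved observations are
excluded from both numerator and denominator (their function status is
unknown, and silently counting them as "absent" would bias every
fraction downward) and reported separately through ``resolved_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Set

import pandas as pd

from .taxdb import ResolutionResult

__all__ = [
    "CommunityProfile",
    "ProfileError",
    "read_abundance_table",
    "compute_occurrence",
    "compute_relative_abundance",
    "profile_samples",
    "write_profile_tables",
]

#: Name given to the single pseudo-sample emitted when no abundance table
#: is supplied (the whole affiliation file is then one community).
PSEUDO_SAMPLE = "community"


class ProfileError(ValueError):
    """Inconsistent profile inputs (unknown ids, empty communities, ...)."""


@dataclass(frozen=True)
class CommunityProfile:
    """One sample's function profile.

    ``occurrence`` and ``abundance`` map function name -> fraction in
    [0, 1]; ``abundance`` is None when no abundance table was supplied.
    ``resolved_fraction`` is the share of observations that resolved
    against the database (abundance-weighted when abundances exist).
    """

    sample_id: str
    occurrence: pd.Series
    abundance: pd.Series | None
    resolved_fraction: float


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    """TSV with first column observation_name, one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if (df.to_numpy() < 0).any():
        raise ProfileError(f"{path}: negative abundance entries")
    return df


def compute_occurrence(presence: pd.DataFrame, members: Set[str]) -> pd.Series:
    """occurrence(f) = |{t in members : presence[t, f]}| / |members|."""
    if not members:
        raise ProfileError("no resolved taxa in sample")
    missing = set(members) - set(presence.index)
    if missing:
        raise ProfileError(f"members absent from presence matrix: {sorted(missing)}")
    sub = presence.loc[sorted(members)]
    return sub.sum(axis=0) / float(len(members))


def compute_relative_abundance(
    presence: pd.DataFrame,
    abundances: pd.DataFrame,
    sample: str,
    members: Set[str] | None = None,
) -> pd.Series:
    """abundance(f) = sum of member abundances possessing f / total member abundance."""
    if sample not in abundances.columns:
        raise ProfileError(f"unknown sample {sample!r}")
    col = abundances[sample]
    if members is None:
        members = set(presence.index) & set(col.index[col > 0])
    members_sorted = sorted(members)
    weights = col.reindex(members_sorted).astype(float)
    denom = float(weights.sum())
    if denom <= 0:
        raise ProfileError(f"sample {sample!r}: zero total abundance over resolved members")
    sub = presence.loc[members_sorted]
    return sub.mul(weights, axis=0).sum(axis=0) / denom


def profile_samples(
    presence: pd.DataFrame,
    abundances: pd.DataFrame | None,
    resolutions: Sequence[ResolutionResult],
    definitions: Sequence | None = None,
) -> dict[str, CommunityProfile]:
    """Build one :class:`CommunityProfile` per sample.

    Without an abundance table a single pseudo-sample covering every
    resolved observation is emitted, with occurrence only.
    """
    resolved = {r.observation_id for r in resolutions if r.status == "resolved"}
    all_obs = {r.observation_id for r in resolutions}
    if definitions is not None:
        expected = [d.function_name for d in definitions]
        presence = presence.reindex(columns=expected, fill_value=False)
    profiles: dict[str, CommunityProfile] = {}
    if abundances is None:
        if not all_obs:
            raise ProfileError("no observations supplied")
        members = resolved
        occ = compute_occurrence(presence, members)
        profiles[PSEUDO_SAMPLE] = CommunityProfile(
            sample_id=PSEUDO_SAMPLE,
            occurrence=occ,
            abundance=None,
            resolved_fraction=len(resolved) / len(all_obs),
        )
        return profiles
    unknown = set(abundances.index.astype(str)) - all_obs
    if unknown:
        raise ProfileError(
            f"abundance table references unknown observation ids: {sorted(unknown)}"
        )
    for sample in abundances.columns:
        col = abundances[sample]
        positive = set(col.index[col > 0].astype(str))
        members = resolved & positive
        occ = compute_occurrence(presence, members)
        ab = compute_relative_abundance(presence, abundances, sample, members)
        total = float(col.reindex(sorted(positive)).sum())
        resolved_weight = float(col.reindex(sorted(members)).sum())
        profiles[str(sample)] = CommunityProfile(
            sample_id=str(sample),
            occurrence=occ,
            abundance=ab,
            resolved_fraction=resolved_weight / total if total > 0 else 0.0,
        )
    return profiles


def write_profile_tables(
    profiles: Mapping[str, CommunityProfile], out_dir: str | Path
) -> dict[str, Path]:
    """Write function_occurrence.tsv / function_abundance.tsv / resolution summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = sorted(profiles)
    occ = pd.DataFrame({s: profiles[s].occurrence for s in samples})
    occ.index.name = "function"
    paths: dict[str, Path] = {}
    paths["occurrence"] = out_dir / "function_occurrence.tsv"
    occ.to_csv(paths["occurrence"], sep="\t")
    if all(profiles[s].abundance is not None for s in samples):
        ab = pd.DataFrame({s: profiles[s].abundance for s in samples})
        ab.index.name = "function"
        paths["abundance"] = out_dir / "function_abundance.tsv"
        ab.to_csv(paths["abundance"], sep="\t")
    frac = pd.DataFrame(
        {"resolved_fraction": [profiles[s].resolved_fraction for s in samples]},
        index=pd.Index(samples, name="sample"),
    )
    paths["resolved"] = out_dir / "resolved_fraction.tsv"
    frac.to_csv(paths["resolved"], sep="\t")
    return paths
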