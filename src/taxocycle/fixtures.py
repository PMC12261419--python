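"""Seeded synthetic inputs with known ground truth.

Everything the pipeline consumes — toy profile HMMs, proteomes with
planted marker sequences plus background decoys, taxonomies, abundance
tables, a database archive — can be generated here from an integer seed,
together with truth tables for the expected function-presence matrix and
community profile.  This makes every stage and the end-to-end pipeline
testable without downloading reference data.

Margins are enforced by construction and then checked: a planted
sequence is the profile's consensus peptide and scores at least twice
the profile cutoff; decoys are drawn from the background distribution
with a rejection step discarding any decoy scoring above half the cutoff
on *any* profile in the collection, so recovery tests cannot flake.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .hmmscan import (
    AMINO_ACIDS,
    ProfileHMM,
    ScoringError,
    viterbi_score,
    write_hmm_file,
)
from .rules import FunctionDefinition, evaluate_formula, format_formula, formula_leaves
from .taxdb import create_db

__all__ = [
    "FixtureTaxon",
    "FixtureSpec",
    "FixtureBundle",
    "make_toy_hmm",
    "random_profile",
    "random_sequence",
    "make_synthetic_community",
    "random_community_spec",
]

_AA_IDX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def make_toy_hmm(
    consensus: str,
    sharpness: float = 1.0,
    seed: int = 0,
    name: str | None = None,
    cutoff_bits: float | None = None,
) -> ProfileHMM:
    """Profile whose match state i emits consensus residue i with
    probability ``sharpness`` (remainder uniform over the other 19).

    Background is uniform, match->match transitions are unit, and the
    insert/delete branches carry zero probability, so the consensus
    peptide scores exactly ``len * log2(sharpness * 20)`` bits.
    """
    consensus = consensus.upper()
    if not 3 <= len(consensus) <= 10:
        raise ValueError("consensus length must be between 3 and 10")
    if not 0.5 < sharpness <= 1.0:
        raise ValueError("sharpness must lie in (0.5, 1]")
    bad = [c for c in consensus if c not in _AA_IDX]
    if bad:
        raise ValueError(f"invalid peptide characters {bad!r}")
    m = len(consensus)
    match = np.full((m, 20), (1.0 - sharpness) / 19.0)
    for i, aa in enumerate(consensus):
        match[i, _AA_IDX[aa]] = sharpness
    insert = np.full((m, 20), 1.0 / 20.0)
    transitions = np.zeros((m + 1, 7))
    transitions[:, 0] = 1.0  # m->m (node 0: begin->M1, node M: M->end)
    transitions[:, 3] = 1.0  # i->m (unreachable, kept normalized)
    transitions[:, 5] = 1.0  # d->m
    hmm = ProfileHMM(
        name=name or f"toy_{consensus}",
        length=m,
        match_emissions=match,
        insert_emissions=insert,
        transitions=transitions,
        background=np.full(20, 1.0 / 20.0),
        cutoff_bits=cutoff_bits,
    )
    hmm.validate()
    return hmm


def random_profile(seed: int, length: int = 3, name: str | None = None) -> ProfileHMM:
    """A fully random (but valid) profile, for oracle-equivalence tests.

    All transition branches get positive probability, so insert and
    delete states are exercised by the dynamic program.
    """
    rng = np.random.default_rng(seed)

    def rows(n: int, k: int) -> np.ndarray:
        r = rng.random((n, k)) + 0.05
        return r / r.sum(axis=1, keepdims=True)

    transitions = np.zeros((length + 1, 7))
    transitions[:, 0:3] = rows(length + 1, 3)
    transitions[:, 3:5] = rows(length + 1, 2)
    transitions[:, 5:7] = rows(length + 1, 2)
    hmm = ProfileHMM(
        name=name or f"random_{seed}",
        length=length,
        match_emissions=rows(length, 20),
        insert_emissions=rows(length, 20),
        transitions=transitions,
        background=rows(1, 20)[0],
    )
    hmm.validate()
    return hmm


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


# ---------------------------------------------------------------------------
# Synthetic communities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureTaxon:
    name: str
    lineage: tuple[tuple[str, str], ...]  # (rank label, name), broad -> specific
    planted: tuple[str, ...]  # profile identifiers planted in the proteome


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    taxa: tuple[FixtureTaxon, ...]
    decoys_per_proteome: int = 10
    samples: tuple[tuple[str, Mapping[str, int]], ...] = ()


@dataclass(frozen=True)
class FixtureBundle:
    """Paths of everything a pipeline run needs, plus the truth tables."""

    root: Path
    affiliations: Path
    abundances: Path | None
    archive: Path
    rules: Path
    profiles: Path
    presence_truth: Path
    profile_truth: Path
    observation_taxa: Mapping[str, str]  # observation id -> taxon name


def _default_defs() -> list[FunctionDefinition]:
    from .rules import default_definitions

    return default_definitions()


def _profile_map(profiles: Sequence[ProfileHMM]) -> dict[str, ProfileHMM]:
    return {p.name: p for p in profiles}


def _decoy(
    rng: np.random.Generator,
    profiles: Sequence[ProfileHMM],
    max_tries: int = 200,
) -> str:
    """Background-distributed sequence scoring <= 0.5x cutoff on every profile."""
    for _ in range(max_tries):
        seq = random_sequence(rng, int(rng.integers(20, 41)))
        ok = True
        for p in profiles:
            cutoff = p.cutoff_bits if p.cutoff_bits is not None else 40.0
            score, _span = viterbi_score(p, seq)
            if score > 0.5 * cutoff:
                ok = False
                break
        if ok:
            return seq
    raise ScoringError("decoy rejection did not converge; cutoffs too permissive")


def make_synthetic_community(
    spec: FixtureSpec,
    out_dir: str | Path,
    definitions: Sequence[FunctionDefinition] | None = None,
    profiles: Sequence[ProfileHMM] | None = None,
) -> FixtureBundle:
    """Materialize a complete synthetic study with analytic ground truth.

    Outputs are byte-deterministic in the seed.  The truth community
    profile is computed with exact rational arithmetic from the spec's
    integer abundances, independent of the community module.
    """
    out_dir = Path(out_dir)
    names = [t.name for t in spec.taxa]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate taxon names: {dupes}")
    if definitions is None:
        definitions = _default_defs()
    if profiles is None:
        from .markers import default_profiles

        profiles = default_profiles()
    pmap = _profile_map(profiles)
    needed: set[str] = set()
    for d in definitions:
        needed |= formula_leaves(d.formula)
    for t in spec.taxa:
        needed |= set(t.planted)
    missing = needed - set(pmap)
    if missing:
        raise ValueError(f"no profile for identifiers: {sorted(missing)}")
    used_profiles = [pmap[n] for n in sorted(needed)]

    rng = np.random.default_rng(spec.seed)
    (out_dir / "truth").mkdir(parents=True, exist_ok=True)
    db_input = out_dir / "db_input"

    # --- proteomes with planted motifs + decoys, margin-checked
    for t in spec.taxa:
        folder = db_input / t.name.replace(" ", "_")
        folder.mkdir(parents=True, exist_ok=True)
        fasta_lines: list[str] = []
        annot_lines = ["cluster_id\tprotein_members\tannotation_labels"]
        for prof_name in t.planted:
            prof = pmap[prof_name]
            cutoff = prof.cutoff_bits if prof.cutoff_bits is not None else 40.0
            seq = "".join(
                AMINO_ACIDS[int(np.argmax(prof.match_emissions[i]))]
                for i in range(prof.length)
            )
            score, _span = viterbi_score(prof, seq)
            if score < 2.0 * cutoff:
                raise ScoringError(
                    f"planted motif for {prof_name} scores {score:.2f} < 2x cutoff"
                )
            for other in used_profiles:
                if other.name == prof_name:
                    continue
                ocut = other.cutoff_bits if other.cutoff_bits is not None else 40.0
                oscore, _ = viterbi_score(other, seq)
                if oscore > 0.5 * ocut:
                    raise ScoringError(
                        f"planted motif for {prof_name} cross-scores "
                        f"{oscore:.2f} on {other.name}"
                    )
            cid = f"{t.name.replace(' ', '_')}_planted_{prof_name}"
            fasta_lines += [f">{cid}", seq]
            annot_lines.append(f"{cid}\t{cid}_m1,{cid}_m2\t{prof_name}")
        for k in range(spec.decoys_per_proteome):
            seq = _decoy(rng, used_profiles)
            cid = f"{t.name.replace(' ', '_')}_decoy_{k}"
            fasta_lines += [f">{cid}", seq]
            annot_lines.append(f"{cid}\t{cid}_m1\tdecoy")
        (folder / "consensus.faa").write_text("\n".join(fasta_lines) + "\n")
        (folder / "annotations.tsv").write_text("\n".join(annot_lines) + "\n")
        (folder / "metadata.json").write_text(
            json.dumps(
                {
                    "taxon_name": t.name,
                    "rank": t.lineage[-1][0],
                    "proteome_count": int(rng.integers(6, 21)),
                },
                indent=1,
            )
        )

    archive, _excluded = create_db(db_input, out_dir / "database.zip", min_proteomes=5)

    # --- affiliations and abundances
    obs_taxa = {f"ASV_{i + 1}": t.name for i, t in enumerate(spec.taxa)}
    aff_lines = ["observation_name\ttaxonomic_affiliation"]
    for i, t in enumerate(spec.taxa):
        lineage = ";".join(name for _rank, name in t.lineage)
        aff_lines.append(f"ASV_{i + 1}\t{lineage}")
    affiliations = out_dir / "affiliations.tsv"
    affiliations.write_text("\n".join(aff_lines) + "\n")

    abundances: Path | None = None
    if spec.samples:
        sample_ids = [s for s, _ in spec.samples]
        ab_lines = ["observation_name\t" + "\t".join(sample_ids)]
        for i, t in enumerate(spec.taxa):
            row = [f"ASV_{i + 1}"] + [str(int(ab.get(t.name, 0))) for _s, ab in spec.samples]
            ab_lines.append("\t".join(row))
        abundances = out_dir / "abundances.tsv"
        abundances.write_text("\n".join(ab_lines) + "\n")

    # --- rules and profiles as files
    rules_path = out_dir / "rules.tsv"
    rules_path.write_text(
        "function_name\tcycle\tformula\n"
        + "\n".join(
            f"{d.function_name}\t{d.cycle}\t{format_formula(d.formula)}" for d in definitions
        )
        + "\n"
    )
    profiles_path = write_hmm_file(used_profiles, out_dir / "profiles.hmm")

    # --- analytic truth tables
    presence: dict[str, dict[str, bool]] = {}
    for i, t in enumerate(spec.taxa):
        present = set(t.planted)
        presence[f"ASV_{i + 1}"] = {
            d.function_name: evaluate_formula(d.formula, present) for d in definitions
        }
    func_names = [d.function_name for d in definitions]
    pt_lines = ["observation\t" + "\t".join(func_names)]
    for obs in sorted(presence):
        pt_lines.append(
            obs + "\t" + "\t".join(str(int(presence[obs][f])) for f in func_names)
        )
    presence_truth = out_dir / "truth" / "presence_truth.tsv"
    presence_truth.write_text("\n".join(pt_lines) + "\n")

    profile_truth = out_dir / "truth" / "profile_truth.tsv"
    if spec.samples:
        header = ["function"]
        for s, _ in spec.samples:
            header += [f"{s}:occurrence", f"{s}:abundance"]
        rows = []
        for f in func_names:
            row = [f]
            for _s, ab in spec.samples:
                members = [
                    (f"ASV_{i + 1}", int(ab.get(t.name, 0)))
                    for i, t in enumerate(spec.taxa)
                    if int(ab.get(t.name, 0)) > 0
                ]
                have = [(o, w) for o, w in members if presence[o][f]]
                occ = Fraction(len(have), len(members))
                wsum = sum(w for _o, w in members)
                abf = Fraction(sum(w for _o, w in have), wsum)
                row += [repr(float(occ)), repr(float(abf))]
            rows.append("\t".join(row))
        profile_truth.write_text("\t".join(header) + "\n" + "\n".join(rows) + "\n")
    else:
        rows = ["function\tcommunity:occurrence"]
        n = len(spec.taxa)
        for f in func_names:
            occ = Fraction(sum(1 for o in presence if presence[o][f]), n)
            rows.append(f"{f}\t{float(occ)!r}")
        profile_truth.write_text("\n".join(rows) + "\n")

    return FixtureBundle(
        root=out_dir,
        affiliations=affiliations,
        abundances=abundances,
        archive=archive,
        rules=rules_path,
        profiles=profiles_path,
        presence_truth=presence_truth,
        profile_truth=profile_truth,
        observation_taxa=obs_taxa,
    )


_LINEAGE_PHYLA = ("Bacillota", "Pseudomonadota", "Euryarchaeota")
_LINEAGE_CLASSES = ("Clostridia", "Gammaproteobacteria", "Methanomicrobia")


def random_community_spec(
    seed: int,
    n_taxa: int = 6,
    decoys_per_proteome: int = 12,
    n_samples: int = 2,
    definitions: Sequence[FunctionDefinition] | None = None,
) -> FixtureSpec:
    """A seeded random community over the packaged marker inventory."""
    if definitions is None:
        definitions = _default_defs()
    leaves: set[str] = set()
    for d in definitions:
        leaves |= formula_leaves(d.formula)
    inventory = sorted(leaves)
    rng = np.random.default_rng(seed)
    taxa = []
    for i in range(n_taxa):
        k = int(rng.integers(2, min(5, len(inventory)) + 1))
        planted = tuple(sorted(rng.choice(inventory, size=k, replace=False).tolist()))
        phylum = _LINEAGE_PHYLA[i % len(_LINEAGE_PHYLA)]
        klass = _LINEAGE_CLASSES[i % len(_LINEAGE_CLASSES)]
        name = f"Genus{seed}_{i}"
        taxa.append(
            FixtureTaxon(
                name=name,
                lineage=(
                    ("kingdom", "Bacteria"),
                    ("phylum", phylum),
                    ("class", klass),
                    ("order", f"Order{i % 2}"),
                    ("family", f"Family{i}"),
                    ("genus", name),
                ),
                planted=planted,
            )
        )
    samples = tuple(
        (
            f"S{j + 1}",
            {t.name: int(rng.integers(1, 51)) for t in taxa},
        )
        for j in range(n_samples)
    )
    return FixtureSpec(
        seed=seed,
        taxa=tuple(taxa),
        decoys_per_proteome=decoys_per_proteome,
        samples=samples,
    )
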