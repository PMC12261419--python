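import json
from pathlib import Path

import pytest

from taxocycle.fixtures import make_synthetic_community, random_community_spec
from taxocycle.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def community_bundle(tmp_path_factory):
    """One small seeded community shared by taxdb/pipeline tests."""
    spec = random_community_spec(11, n_taxa=5, decoys_per_proteome=8, n_samples=2)
    return make_synthetic_community(spec, tmp_path_factory.mktemp("community"))


@pytest.fixture(scope="session")
def pipeline_output(community_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_out")
    report = run_pipeline(
        PipelineConfig(
            affiliations=community_bundle.affiliations,
            archive=community_bundle.archive,
            output_dir=out,
            abundances=community_bundle.abundances,
            profiles=community_bundle.profiles,
            rules=community_bundle.rules,
            cores=1,
        )
    )
    return out, report


def make_taxon_folder(root: Path, name: str, rank: str, count: int, clusters):
    """Write one create_db input folder; clusters = [(cid, seq, members, labels)]."""
    folder = root / name.replace(" ", "_")
    folder.mkdir(parents=True)
    fasta, annot = [], ["cluster_id\tprotein_members\tannotation_labels"]
    for cid, seq, members, labels in clusters:
        fasta += [f">{cid}", seq]
        annot.append(f"{cid}\t{','.join(members)}\t{','.join(labels)}")
    (folder / "consensus.faa").write_text("\n".join(fasta) + "\n")
    (folder / "annotations.tsv").write_text("\n".join(annot) + "\n")
    (folder / "metadata.json").write_text(
        json.dumps({"taxon_name": name, "rank": rank, "proteome_count": count})
    )
    return folder
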