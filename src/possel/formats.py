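"""Tabular and domain file formats.

All tabular I/O is plain TSV with a header line and ``#`` comments; floats
are written with 10 significant digits so repeated runs are byte-identical.
Domain formats are OBO (ontology), newick (trees) and two-column TSVs for
associations and gene sets.  Column layouts are documented in
docs/FORMATS.md.
"""

from __future__ import annotations

import io
import json
import os
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

FLOAT_FORMAT = "%.10g"


def write_tsv(df: pd.DataFrame, path, comments: Sequence[str] = ()) -> None:
    """Write a TSV with optional leading '#' comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv`; raises with the offending line
    number on a malformed row.

    Only whole lines starting with '#' are comments — a '#' inside a field
    (e.g. branch labels like ``#1``) is data.
    """
    with open(path) as fh:
        body = "".join(line for line in fh if not line.startswith("#"))
    try:
        return pd.read_csv(io.StringIO(body), sep="\t", **kwargs)
    except (pd.errors.ParserError, ValueError, TypeError) as err:
        raise ValueError(f"{path}: malformed TSV ({err})") from err


# -- replicate runs ---------------------------------------------------------

RUN_COLUMNS = ["family_id", "branch_id", "hypothesis", "run", "lnl"]


def write_runs(runs: pd.DataFrame, path) -> None:
    write_tsv(runs[RUN_COLUMNS], path)


def read_runs(path) -> pd.DataFrame:
    # "null" is a hypothesis label, not a missing value
    df = read_tsv(path, dtype={"family_id": str, "branch_id": str,
                               "hypothesis": str, "run": int, "lnl": float},
                  keep_default_na=False, na_values=[""])
    missing = set(RUN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


# -- test records / family scores / enrichment ------------------------------


def write_records(records: pd.DataFrame, path) -> None:
    write_tsv(records, path)


def read_records(path) -> pd.DataFrame:
    return read_tsv(path, dtype={"family_id": str, "branch_id": str})


def write_scores(scores: pd.DataFrame, path) -> None:
    write_tsv(scores[["family_id", "n_branches_used", "mean_lrt", "transformed"]], path)


def read_scores(path) -> pd.DataFrame:
    return read_tsv(path, dtype={"family_id": str})


def write_enrichment(results: pd.DataFrame, path) -> None:
    write_tsv(results, path)


# -- associations / gene sets -----------------------------------------------


def write_associations(assoc: pd.DataFrame, path) -> None:
    write_tsv(assoc[["gene", "term"]], path)


def read_associations(path) -> pd.DataFrame:
    df = read_tsv(path, dtype=str)
    if not {"gene", "term"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'gene' and 'term'")
    return df


def write_gene_sets(sets: Mapping[str, Sequence[str]], path) -> None:
    """Gene-set definition file: name TAB comma-separated gene ids."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("name\tgenes\n")
        for name in sorted(sets):
            fh.write(f"{name}\t{','.join(sets[name])}\n")


def read_gene_sets(path) -> dict[str, list[str]]:
    df = read_tsv(path, dtype=str)
    return {row.name: row.genes.split(",")
            for row in df.itertuples(index=False)}


# -- trees / ontology / truth -----------------------------------------------


def write_trees(trees: Mapping[str, str], directory) -> None:
    """One newick file per family under `directory`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for fam, newick in trees.items():
        (directory / f"{fam}.nwk").write_text(newick.rstrip() + "\n")


def read_trees(directory) -> dict[str, str]:
    directory = Path(directory)
    return {p.stem: p.read_text().strip() for p in sorted(directory.glob("*.nwk"))}


def write_obo(text: str, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(text)


def write_dataset(dataset, directory) -> dict[str, str]:
    """Write a SyntheticDataset to `directory`; returns the path map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "runs": str(directory / "replicate_runs.tsv"),
        "associations": str(directory / "associations.tsv"),
        "ontology": str(directory / "ontology.obo"),
        "species_tree": str(directory / "species_tree.nwk"),
        "trees": str(directory / "trees"),
        "truth_tests": str(directory / "truth_tests.tsv"),
        "truth_terms": str(directory / "truth_terms.tsv"),
    }
    write_runs(dataset.replicate_runs, paths["runs"])
    write_associations(dataset.annotations, paths["associations"])
    write_obo(dataset.ontology_obo, paths["ontology"])
    Path(paths["species_tree"]).write_text(dataset.species_newick.rstrip() + "\n")
    write_trees(dataset.family_trees, paths["trees"])
    write_tsv(dataset.truth_tests, paths["truth_tests"])
    write_tsv(dataset.truth_terms, paths["truth_terms"])
    return paths


def write_config(config: Mapping, path) -> None:
    """Resolved run configuration, written next to the outputs."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(dict(config), fh, indent=2, sort_keys=True, default=str)
        fh.write(os.linesep)
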