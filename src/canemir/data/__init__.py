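"""Bundled reference data: sugarcane mature miRNAs and worked examples."""

from __future__ import annotations

from importlib.resources import as_file, files

import pandas as pd


def mature_reference():
    """The 30 sugarcane (ssp/spp) mature miRNA sequences, 18 families."""
    from ..io import read_fasta

    with as_file(files(__package__) / "sugarcane_matures.fasta") as path:
        return read_fasta(path)


def target_examples() -> pd.DataFrame:
    """Worked miRNA:target alignments with their expectation scores.

    ``clean == 1`` rows are reproduced exactly by the default scoring scheme;
    see the file header for the meaning of the flag.
    """
    with as_file(files(__package__) / "target_examples.tsv") as path:
        return pd.read_csv(path, sep="\t", comment="#")


def library_category_counts() -> pd.DataFrame:
    """Example per-category unique/total read tallies for one library."""
    with as_file(files(__package__) / "library_category_counts.tsv") as path:
        return pd.read_csv(path, sep="\t", comment="#")
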