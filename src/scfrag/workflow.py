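"""Cohort-level orchestration: per-sample metrics → feature bundles.

Glue between the single-sample metric modules and the group-comparison /
integration layer.  Used by the CLI; importable directly for scripted runs.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .end_motif import gquad_prevalence, motif_profile
from .fragments_io import GenomeModel, SampleFragments, make_bins
from .genome_features import bin_coverage, fragment_score, mito_fraction
from .microbiome import TaxaTable, microbial_fraction, rank_abundance, shannon_alpha
from .size_profile import build_histogram, detect_extrema, peak_valley_index


def sample_scalar_metrics(
    sample: SampleFragments,
    lo: int = 35,
    hi: int = 300,
    lookahead: int = 1,
    delta: float = 0.0001,
) -> dict[str, float]:
    """Per-sample scalar fragmentomic metrics.

    Sequence-dependent metrics (motif entropy, G4 prevalence) are included
    only when the sample carries sequences.
    """
    hist = build_histogram(sample, lo, hi)
    pv = detect_extrema(hist, lookahead=lookahead, delta=delta)
    out = {
        "peak_valley_index": peak_valley_index(pv),
        "fragment_score": fragment_score(sample),
        "mito_fraction_pct": mito_fraction(sample),
    }
    if sample.seqs is not None and any(s is not None for s in sample.seqs):
        prof = motif_profile(sample, k=4)
        out["motif_entropy_bits"] = prof.entropy_bits
        out["g4_prevalence_pct"] = gquad_prevalence(sample)
    return out


def cohort_feature_bundles(
    samples: Mapping[str, SampleFragments],
    taxa: TaxaTable | None = None,
    genome: GenomeModel | None = None,
    include_bins: bool = True,
    include_motif_freqs: bool = True,
) -> dict[str, pd.DataFrame]:
    """Assemble per-module feature bundles for a cohort.

    Returns ``{module_name: DataFrame(samples × features)}`` covering
    fragmentomics scalars, per-bin coverage and fragment scores
    (karyogram), 256 end-motif frequencies, and microbial metrics when a
    taxa table is supplied.
    """
    genome = genome or GenomeModel.grch38()
    bins = make_bins(genome, genome.autosomes)
    ids = list(samples)

    scalars, motif_rows, cov_rows, fs_rows = {}, {}, {}, {}
    for sid, sample in samples.items():
        scalars[sid] = sample_scalar_metrics(sample)
        if include_bins:
            table = bin_coverage(sample, bins)
            labels = [
                f"{c}:{s}-{e}"
                for c, s, e in zip(table["contig"], table["start"], table["end"])
            ]
            cov_rows[sid] = pd.Series(table["coverage_pct"].to_numpy(), index=labels)
            fs_rows[sid] = pd.Series(table["fragment_score"].to_numpy(), index=labels)
        if include_motif_freqs and sample.seqs is not None:
            prof = motif_profile(sample, k=4)
            motif_rows[sid] = pd.Series(prof.freqs)

    bundles: dict[str, pd.DataFrame] = {
        "fragmentomics": pd.DataFrame.from_dict(scalars, orient="index").loc[ids]
    }
    if include_bins:
        cov = pd.DataFrame.from_dict(cov_rows, orient="index").loc[ids]
        bundles["karyogram_coverage"] = cov.add_prefix("cov_")
        fs = pd.DataFrame.from_dict(fs_rows, orient="index").loc[ids]
        bundles["fragment_score_bins"] = fs.add_prefix("fs_")
    if motif_rows:
        bundles["end_motif"] = pd.DataFrame.from_dict(motif_rows, orient="index").loc[ids]
    if taxa is not None:
        micro = {}
        totals = taxa.totals()
        for sid in ids:
            n_micro = int(totals.get(sid, 0))
            frac = microbial_fraction(samples[sid].n_total, n_micro)
            micro[sid] = {"microbial_fraction_pct": frac["pct_of_classified"]}
        genus = rank_abundance(taxa, "genus")
        for sid in ids:
            if sid in genus.index:
                micro[sid]["alpha_diversity_shannon"] = shannon_alpha(genus.loc[sid])
            else:
                micro[sid]["alpha_diversity_shannon"] = np.nan
        bundles["microbiome"] = pd.DataFrame.from_dict(micro, orient="index").loc[ids]
    return bundles
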