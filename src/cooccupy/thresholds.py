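"""The pipeline's analysis constants in one place.

Defaults reflect the study conditions the pipeline was designed around:
a two-fold / 5% FDR differential-expression filter, tissue enrichment at
1.5x the cross-tissue mean, 150 bp summit windows scanned at a 0.70
relative PWM score against a 10x dinucleotide-shuffled background,
+/-2 kb density windows, a 50 bp site-clustering distance, the ">5 sites
per peak" multiplicity cut, and a +/-1 kb promoter margin around the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AnalysisThresholds:
    fold_change: float = 2.0          # DE filter: |log2FC| > log2(fold_change)
    fdr: float = 0.05                 # DE filter: FDR < fdr
    spatial_ratio: float = 1.5        # enriched tissue: value > ratio * mean
    summit_window: int = 150          # bp, motif-scanning window around summit
    motif_rel_threshold: float = 0.70 # relative PWM score cut
    n_shuffles: int = 10              # dinucleotide shuffles per window
    heatmap_flank: int = 2000         # bp each side of summit for density
    heatmap_bin: int = 50             # bp per density bin
    cluster_bp: int = 50              # Sox/Tcf site spacing call
    multi_site_threshold: int = 5     # "multiple sites": count strictly greater
    promoter_margin: int = 1000       # bp around TSS


DEFAULTS = AnalysisThresholds()
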