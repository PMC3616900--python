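"""Cross-lineage comparison: motif categories and the published tables.

First categorizes two synthetic PWMs by mismatches at high-information
positions (category I = well conserved, II = 2-4 mismatches, III =
diverged), then reproduces the summary statistics of the packaged
30-genome reconstruction tables.
"""

import numpy as np

from regulonkit.comparative import align_pwms
from regulonkit.motifs import PWM
from regulonkit.reporting import (
    load_table1,
    load_table2,
    summarize_distribution,
    summarize_network,
)


def pwm_from_consensus(consensus, p=0.9):
    counts = np.full((len(consensus), 4), (1 - p) / 3 * 100)
    for i, b in enumerate(consensus):
        counts[i, "ACGT".index(b)] = p * 100
    return PWM(counts)


a = pwm_from_consensus("TTGACAATGTTGTCAA")
b = pwm_from_consensus("TAGACCATGTTGTGAA")  # three consensus edits
cmp = align_pwms(a, b, tf_group="demo")
print(f"motif comparison: {cmp.mismatches} mismatches at conserved positions "
      f"-> category {cmp.category}")

stats = summarize_network(load_table1())
dist = summarize_distribution(load_table2())
print(f"mean regulons per genome: {stats.mean['tfs']}")
print(f"regulons per genome range: {stats.min['tfs'][1]}-{stats.max['tfs'][1]}")
print(f"target genes per lineage: "
      f"Streptococcaceae {stats.totals['Streptococcaceae']['target_genes']}, "
      f"Lactobacillaceae {stats.totals['Lactobacillaceae']['target_genes']}")
print(f"orthologous TF regulons: {dist.total} "
      f"({dist.both_lineages} shared, {dist.only_first} + {dist.only_second} "
      f"lineage-specific)")
# These numbers are recomputed from the per-genome fixture rows, not
# stored as constants.
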