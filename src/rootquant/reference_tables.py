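"""Published six-class reference summaries for the two indices.

Group summaries (n, mean, sample SD, range) of the t-index and ml-index
over a 180-image dataset of stained root segments, visually scored into
the six Trouvelot colonization classes (30 images per class).  These
printed summaries are sufficient inputs for the whole statistics layer:
one-way ANOVA, Bonferroni post hoc, and grand means can all be
reconstructed from (n, mean, SD) alone, which is how the package
validates its :mod:`rootquant.stats_eval` implementation against the
published tables.
"""

from .stats_eval import GroupSummary

__all__ = ["T_INDEX_SUMMARIES", "ML_INDEX_SUMMARIES", "N_PER_CLASS"]

N_PER_CLASS = 30

#: t-index (brightness thresholding at cutoff 100) per visual class.
T_INDEX_SUMMARIES = (
    GroupSummary(group=1, n=30, mean=1.01, sd=1.19, value_range=5.58),
    GroupSummary(group=2, n=30, mean=5.87, sd=4.40, value_range=16.44),
    GroupSummary(group=3, n=30, mean=14.39, sd=10.19, value_range=38.98),
    GroupSummary(group=4, n=30, mean=15.17, sd=8.36, value_range=28.64),
    GroupSummary(group=5, n=30, mean=29.75, sd=13.22, value_range=51.33),
    GroupSummary(group=6, n=30, mean=29.97, sd=11.68, value_range=45.35),
)

#: ml-index (trained pixel classification) per visual class.
ML_INDEX_SUMMARIES = (
    GroupSummary(group=1, n=30, mean=6.42, sd=6.20, value_range=18.60),
    GroupSummary(group=2, n=30, mean=7.88, sd=8.64, value_range=41.81),
    GroupSummary(group=3, n=30, mean=17.30, sd=11.75, value_range=40.66),
    GroupSummary(group=4, n=30, mean=26.79, sd=10.59, value_range=49.60),
    GroupSummary(group=5, n=30, mean=44.15, sd=11.37, value_range=37.43),
    GroupSummary(group=6, n=30, mean=48.43, sd=8.84, value_range=33.87),
)
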