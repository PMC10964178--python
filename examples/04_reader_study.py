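"""Visual-Turing-test statistics from a reader study.

Two blinded readers each saw 60 images (30 real H&E, 30 virtually stained)
and called each one "real" or "virtual".  With "real" as the positive
class, sensitivity measures how often real histology is recognised and
specificity how often virtual staining is caught; specificity near or
below chance means the virtual images pass for real.
"""

from octstain.metrics import ConfusionCounts, reader_study_stats

# reader A called 42 images "real", 19 of them virtual;
# reader B called 33 images "real", 15 of them virtual
reader_a = ConfusionCounts(n_real_called_real=23, n_real_called_virtual=7,
                           n_virtual_called_real=19, n_virtual_called_virtual=11)
reader_b = ConfusionCounts(n_real_called_real=18, n_real_called_virtual=12,
                           n_virtual_called_real=15, n_virtual_called_virtual=15)

report = reader_study_stats([reader_a, reader_b])
for i, stats in enumerate(report["per_reader"]):
    pretty = {k: round(v, 3) for k, v in stats.items()}
    print(f"reader {'AB'[i]}: {pretty}")
avg = {k: round(v, 2) for k, v in report["average"].items()}
print(f"averages: {avg}")
print("Average sensitivity 0.68 but specificity 0.43: readers recognise "
      "real histology more often than they catch virtual images, i.e. the "
      "virtual staining is close to indistinguishable.")
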