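"""Contrast the motif consensus under retained versus lost peaks.

The genome is scanned for the 22-bp motif; each promoter peak is assigned its
single closest occurrence within 250 bp of the summit; the matched 22-mers
are stacked into one consensus matrix per category.  The information-content
contrast shows a selectively degraded 3' half under the lost peaks, while
the 5' half is equally sharp in both classes.
"""

from occuclass import SyntheticConfig, run_pipeline
from occuclass.motifs import HALF_SPLIT

result = run_pipeline(SyntheticConfig(seed=7))

for cat, (pwm, ic) in result.consensus.items():
    print(f"{cat:12s} consensus {pwm.consensus()}  "
          f"5' mean IC {ic[:HALF_SPLIT].mean():.2f} bits, "
          f"3' mean IC {ic[HALF_SPLIT:].mean():.2f} bits")

ic = result.ic_contrast
print(f"\nIC difference (common - F80L_absent): "
      f"5' half {ic['delta_5p']:+.2f} bits, 3' half {ic['delta_3p']:+.2f} bits")
print(f"peaks with no motif within +/-1000 bp of the summit: "
      f"{100 * result.summary['tam_absent_fraction_f80l_absent']:.0f}% of lost peaks vs "
      f"{100 * result.summary['tam_absent_fraction_common']:.0f}% of common peaks")

# A positive 3'-half difference with a near-zero 5'-half difference means the
# mutant tolerates 5'-half variation but not a weakened 3' block.
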