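"""Comparing two forecasters with the evaluation suite.

Builds two forecast error series of genuinely different accuracy and runs
the Diebold-Mariano test, the accuracy growth rate and the stability
measure on them.
"""

import numpy as np

from btsforecast import accuracy_growth, dm_test, mape, var_residuals

rng = np.random.default_rng(0)
y = rng.uniform(1.5, 3.5, 150)               # truths, bounded away from zero
good = y + 0.10 * rng.normal(size=y.size)    # accurate forecaster
poor = y + 0.30 * rng.normal(size=y.size)    # three times the error sd

m_good, m_poor = mape(y, good), mape(y, poor)
print(f"MAPE: good {m_good:.2f}%  poor {m_poor:.2f}%")
print(f"accuracy growth rate of good over poor: {accuracy_growth(m_poor, m_good):.1f}%")

res = dm_test(poor - y, good - y)
print(f"\nDM statistic {res.statistic:.3f} vs critical values {res.critical_values}")
print(f"reject equal accuracy at 90/95/99%: {res.reject_90}/{res.reject_95}/{res.reject_99}")

print(f"\nstability (residual variance): good {var_residuals(y, good):.4f}, "
      f"poor {var_residuals(y, poor):.4f}")
print("\nA positive DM value above 2.58 says the first error series is")
print("significantly worse at the 1% level under squared-error loss.")
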