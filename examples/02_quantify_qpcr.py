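"""2^-ddCt quantification round trip.

Synthesises triplicate Ct records from known expression values, quantifies
them back with the returned calibrator dCt, and shows the recovery is exact
at zero technical noise and unbiased at realistic noise.
"""

import numpy as np

from circad import default_cohort_config, generate_cohort, generate_ct_records, relative_expression

cohort = generate_cohort(default_cohort_config(seed=4)).head(200)
truth = dict(zip(cohort["id"], cohort["hsa_circRPRD1A"]))

records, cal_dct = generate_ct_records(cohort, "hsa_circRPRD1A", noise_sd=0.0)
errs = [relative_expression(r, cal_dct).value - truth[r.subject_id] for r in records]
print(f"zero noise: max |recovery error| = {max(abs(e) for e in errs):.2e}  (exact round trip)")

records, cal_dct = generate_ct_records(cohort, "hsa_circRPRD1A", noise_sd=0.1, seed=4)
log_err = [np.log(relative_expression(r, cal_dct).value) - np.log(truth[r.subject_id])
           for r in records]
print(f"0.1-cycle Ct noise: mean log-error = {np.mean(log_err):+.4f} "
      f"(sd {np.std(log_err):.4f}) -> unbiased in the log domain")
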