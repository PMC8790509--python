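# trtequate

Monte-Carlo evaluation of **testlet response theory (TRT) models versus
classical IRT models for equating testlet-based test forms** under the
NEAT design (non-equivalent groups with an anchor test) with concurrent
calibration.

Tests are often built from *testlets* — sets of items sharing a common
stimulus such as a reading passage. Responses within a testlet violate the
local independence assumption of unidimensional IRT. This package asks,
by simulation, what that violation costs when two test forms are placed on
one scale by concurrent calibration: it generates NEAT form pairs with
person-by-testlet random effects, calibrates them with either the
classical model or the testlet model, and measures equating error.

It is aimed at psychometricians studying equating designs and local item
dependence, and at anyone needing a fast, tested multiple-group MML-EM
calibrator for the 2PLM / 2PTM / GRM / GRTM families in Python.

## Models

For examinee *i*, item *j* in testlet *d(j)*:

* **2PLM**  `P(y_ij = 1) = logistic(a_j (θ_i − b_j))`
* **2PTM**  `P(y_ij = 1) = logistic(a_j (θ_i − b_j − γ_id(j)))`, `γ_id ~ N(0, σ²_d)`
* **GRM**   `P*_jx(θ) = logistic(a_j (θ_i − b_jx))`, category prob `P_jx = P*_jx − P*_j,x+1`
* **GRTM**  the GRM with `γ_id(j)` inside the logit

`σ²_d` is the *testlet effect*: the larger it is, the stronger the local
dependence. Calibration is marginal maximum likelihood EM with bifactor
dimension reduction for the testlet effects, concurrent across the two
examinee groups (base group fixed at N(0,1), anchor items shared), and
abilities are EAP-scored. Equating error over R replications is summarised
by Bias, SEE and RMSE (with divisor R, so `RMSE² = Bias² + SEE²` exactly).

## Worked example

```python
import numpy as np
from trtequate import (
    SimulationCondition, build_form_pair, sample_persons, generate_responses,
    assemble_concurrent_matrix, replication_rng, ConcurrentCalibrator,
)

cond = SimulationCondition(data_family="dichotomous", testlet_effect="low",
                           testlet_length=5, sample_size=1000, seed=7)
rng = replication_rng(7, 0, 0)
pair = build_form_pair(cond, rng)                       # 60+60 items, 20 shared anchors
base = sample_persons(1000, "base", pair.testlets_for("base"), rng)
new = sample_persons(1000, "new", pair.testlets_for("new"), rng, 0.5)
matrix = assemble_concurrent_matrix(
    generate_responses(pair.base_items, base, rng),
    generate_responses(pair.new_items, new, rng), pair)

cal = ConcurrentCalibrator("2PTM", convergence_tol=1e-3)
cal.fit(matrix, structure=pair)
print(round(cal.group_params_["new_mean"], 2), cal.converged_)

theta_hat = cal.predict(matrix)                          # EAP scores
err = theta_hat[matrix.groups == "new"] - new.thetas
print(round(float(np.sqrt((err**2).mean())), 2))
```

This prints

```
0.49 True
0.29
```

— the estimated new-group ability mean (true shift +0.5, recovered from
the anchor link), a converged EM flag, and the EAP ability RMSE for the
new group under the correctly specified testlet model at this desk-scale
condition.

There is also a CLI for shell use:

```bash
trtequate simulate --study dichotomous --effect low --n 1000 --seed 7 --out run/
trtequate fit --matrix run/responses.tsv --items run/items.tsv --family 2PTM --out fit.json
trtequate study --study dichotomous --reps 50 --seed 7 --out study_out/
trtequate summarize --estimates study_out/ --out tables.tsv
```

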