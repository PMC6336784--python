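"""Generate the fixed dataset for the SCI-regression cross-fit oracle and
fit it with R glm (quasipoisson / quasibinomial).  The printed coefficients
are frozen into tests/test_network.py; the test regenerates the identical
dataset from the same seed and compares sci_regressions output."""
import subprocess
from pathlib import Path

import polysel as ps
from polysel.network import build_mating_matrices, sperm_competition_intensity

ds = ps.simulate_experiment(ps.SimConfig(n_groups=20, seed=42))
sdf = ps.summaries_to_frame(ps.compute_male_summaries(ds.events, ds.paternity, ds.rosters))
mats = build_mating_matrices(ds.events, ds.rosters)
sci = {m.group_id: sperm_competition_intensity(m)[m.focal_index] for m in mats}
df = sdf.copy()
df["sci"] = df["group_id"].map(sci)
df = df.dropna(subset=["sci", "M", "P", "N", "T"])
df["m_std"] = df["M"] / df["M"].mean()
df["sci_std"] = df["sci"] / df["sci"].mean()
df["sired"] = df["T"]
df["unsired"] = (df["M"] * df["N"]) - df["T"]
Path("scratch").mkdir(exist_ok=True)
df.to_csv("scratch/glm_oracle_data.csv", index=False)

rcode = r"""
df <- read.csv("scratch/glm_oracle_data.csv")
df$replicate_id <- factor(df$replicate_id)
ft <- glm(T ~ m_std + sci_std + group_fecundity + replicate_id,
          family=quasipoisson, data=df, control=glm.control(epsilon=1e-12, maxit=100))
fp <- glm(cbind(sired, unsired) ~ sci_std + group_fecundity + replicate_id,
          family=quasibinomial, data=df, control=glm.control(epsilon=1e-12, maxit=100))
opts <- options(digits=12)
print(summary(ft)$coefficients)
print(summary(fp)$coefficients)
"""
print(subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True).stdout)
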