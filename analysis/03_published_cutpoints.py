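"""Cut-point equivalencies and group rates from the published crosswalks.

Uses the packaged published reference crosswalks (not the synthetic run):
finds the target raw cuts closest to the conventional anchor cut-points,
maps the single-item screen's cut across to the work-exhaustion scale on
their shared metric, and demonstrates the aggregated-data route: a burnout
rate on the anchor metric computed from a frequency table of target raw
scores alone.  Writes results/published_cutpoints.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from burnlink.io import load_anchor_cutpoints, load_reference_crosswalk
from burnlink.linking import (
    closest_cutpoint,
    cross_target_cutpoint,
    rates_from_frequency_table,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=2019)
parser.add_argument("--out", type=Path, default=Path("results/published_cutpoints.json"))
args = parser.parse_args()

cuts = load_anchor_cutpoints()
ee, dp = cuts["MBI-EE"], cuts["MBI-DP"]
cw_we = load_reference_crosswalk("pfi_we_to_mbi_ee")
cw_id = load_reference_crosswalk("pfi_id_to_mbi_dp")
cw_mz = load_reference_crosswalk("mzsib_to_mbi_ee")

eq_we = closest_cutpoint(cw_we, ee["t"], ee["raw"])
eq_mz = closest_cutpoint(cw_mz, ee["t"], ee["raw"])
eq_id = closest_cutpoint(cw_id, dp["t"], dp["raw"])
eq_cross = cross_target_cutpoint(cw_mz, eq_mz.target_raw_cut, cw_we)

print(f"MBI-EE >= {ee['raw']} (t = {ee['t']}) ~ PFI-WE >= {eq_we.target_raw_cut} "
      f"(t = {eq_we.target_cut_t})")
print(f"MBI-EE >= {ee['raw']} (t = {ee['t']}) ~ MZSIB  >= {eq_mz.target_raw_cut} "
      f"(t = {eq_mz.target_cut_t})")
print(f"MBI-DP >= {dp['raw']} (t = {dp['t']}) ~ PFI-ID >= {eq_id.target_raw_cut} "
      f"(t = {eq_id.target_cut_t})")
print(f"MZSIB >= {eq_mz.target_raw_cut} ~ PFI-WE >= {eq_cross.target_raw_cut} "
      "(shared exhaustion metric)")

# group-rate demonstration from aggregated data: a synthetic frequency table
rng = np.random.default_rng(args.seed)
raws, counts = np.unique(rng.binomial(16, 0.38, 500), return_counts=True)
freq = dict(zip(raws.tolist(), counts.tolist()))
rate = rates_from_frequency_table(freq, cw_we, ee["t"])
print(f"demo: anchor-metric burnout rate from a PFI-WE frequency table alone: "
      f"{100 * rate:.1f}% at or above t = {ee['t']}")

args.out.parent.mkdir(parents=True, exist_ok=True)
args.out.write_text(json.dumps({
    "pfi_we_cut": eq_we.target_raw_cut,
    "mzsib_cut": eq_mz.target_raw_cut,
    "pfi_id_cut": eq_id.target_raw_cut,
    "mzsib_to_pfi_we": eq_cross.target_raw_cut,
    "demo_rate_from_frequency_table": rate,
}, indent=1))
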