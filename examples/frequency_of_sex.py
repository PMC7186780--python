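"""Estimate how often a facultatively sexual alga goes through meiosis.

Combines a population estimate of the recombination rate (rho = 2*Ne*r*f,
which only accrues in sexual generations) with diversity (theta = 2*Ne*mu,
which accrues every generation) and lab-measured per-meiosis crossover and
per-division mutation rates. The ratio f = (rho/r)/(theta/mu) is the
fraction of generations that are sexual.
"""

from rhoscape import SexFrequencyInputs, frequency_of_sex, generations_to_days, realized_r

inputs = SexFrequencyInputs(
    rho=4.09e-3,     # genome-wide mean population recombination rate per bp
    theta=2.75e-2,   # silent-site nucleotide diversity per bp
    r_cm_mb=12.0,    # crossover rate measured in lab crosses, cM/Mb
    mu=9.63e-10,     # mutation rate per bp per generation (MA lines)
    ne=1.4e7,        # effective population size
)

f, generations = frequency_of_sex(inputs)
days = generations_to_days(generations, inputs.doublings_per_day)
r_realized = realized_r(inputs.rho, inputs.ne)

print(f"frequency of sex f        = {f:.6f}  (meioses per mitosis)")
print(f"generations per sex cycle = {generations:.0f}")
print(f"days per sex cycle        = {days:.0f}  (at {inputs.doublings_per_day} doublings/day)")
print(f"realized r = rho/(2 Ne)   = {r_realized:.4f} cM/Mb")
print()
print("Reading: roughly one sexual cycle per ~840 asexual generations —")
print("about one per year at lab division rates — and a realized per-")
print("generation crossover rate ~3 orders of magnitude below the lab rate.")
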