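"""Niche overlap and randomization tests across the three comparison classes.

Produces one summary row per scenario — Schoener's D, the equivalency p-value
(lower tail: are the niches less interchangeable than random re-labelling
allows?), and both similarity p-values (greater tail: do the niches overlap
more than random placement over their backgrounds would produce?).
"""

from nichecmp import compare_pair, generate_scenario
from nichecmp.synthetic import SCENARIO_NAMES

print(f"{'scenario':<22} {'D':>6} {'p_equiv':>8} {'p_sim_12':>9} {'p_sim_21':>9}")
for name in SCENARIO_NAMES:
    sc = generate_scenario(name, n_per_species=50, seed=7)
    res = compare_pair(*sc.occurrences, *sc.backgrounds, sc.grid, reps=99, seed=7)
    row = res.to_row()
    print(f"{name:<22} {row['D']:>6.3f} {row['p_equiv']:>8.3f} "
          f"{row['p_sim_12']:>9.3f} {row['p_sim_21']:>9.3f}")

print(
    "\nReading the table: diverged allopatric niches overlap weakly (low D)\n"
    "and the equivalency test rejects (p <= 0.05); a shared sympatric niche\n"
    "overlaps strongly and both similarity tests reject — the niches are more\n"
    "alike than their backgrounds alone can explain."
)
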