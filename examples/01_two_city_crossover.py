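"""Two-city system: when does a penalized large city start losing people?

City 1 (population 1e4) is unpenalized; city 2 (population 1e6) carries a
benefit penalty delta.  Under the standard radiation model (delta = 1)
the big city always attracts more movers; beyond a crossover delta* the
direction of net flow reverses — the signature behaviour of the
inequality-aware model.
"""

from ineqrad import crossover_delta, two_city_probabilities

n1, n2 = 10_000, 1_000_000

for delta in (1.0, 1.00003, 1.0001, 1.001):
    p12, p21 = two_city_probabilities(n1, n2, delta)
    tag = "big city wins" if p12 > p21 else "small city wins"
    print(f"delta = {delta:<8g}  p(1->2) = {p12:.4f}  p(2->1) = {p21:.4f}   {tag}")

d_star = crossover_delta(n1, n2)
print(f"\ncrossover delta* = {d_star:.7f}")
print("Beyond delta*, residents of the penalized metropolis are more likely")
print("to move to the small safe town than the other way round.")
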