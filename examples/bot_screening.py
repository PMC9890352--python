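"""Bot filtration on archetypal automated accounts.

Generates one posting record per bot archetype and shows which rule each
trips: a burst of >= 9 posts in one minute, >= 2**14 lifetime posts,
>= 2% of posts at the same exact minute-of-day, or a bot-like username.
"""

from noctograph import bot_flags
from noctograph.synthetic import simulate_bot

for archetype in ("burst", "volume", "periodic", "named"):
    username, epochs = simulate_bot(archetype, seed=5)
    flags = bot_flags(epochs, username)
    fired = [f for f in ("burst", "volume", "periodicity", "name")
             if getattr(flags, f)]
    print(f"{archetype:9s} {username:16s} {len(epochs):6d} posts -> "
          f"flags {fired}, is_bot={flags.is_bot}")

# Survey respondents are exempt from these rules (answering a bedtime poll
# is evidence of humanity); they apply when the model is deployed at scale.
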