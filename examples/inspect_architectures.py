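"""Print the propagated layer-shape tables of the three cascade orders.

Each table lists the feature-map shape after every layer — valid
convolutions shrink by kernel-1, max pools divide — ending in the model's
coordinate output (2 values per regressed point).
"""

from spinealign import (first_order_arch, second_order_arch, shape_table,
                        third_order_arch)

for arch in (first_order_arch(), second_order_arch(6), third_order_arch(8)):
    print(shape_table(arch))
    print()
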