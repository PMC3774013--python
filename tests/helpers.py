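"""Shared test helpers."""


def open_all_gates(age_group, registry, include_maternal=True):
    """Responses that answer every gate of the age group 'yes'."""
    responses = {}
    for ind in registry.for_age_group(age_group, "cod_related"):
        if registry.is_gate(ind.indicator_id):
            if not include_maternal and ind.maternal:
                responses[ind.indicator_id] = "no"
            else:
                responses[ind.indicator_id] = "yes"
    return responses
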