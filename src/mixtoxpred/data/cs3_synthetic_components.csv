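# product_name: synthetic perfluorinated carboxylic acid mixture (synthetic stand-in parameters)
# output_unit: uM
# endpoint_type: EC50
name,cas,component_type,physical_state,composition_percent,molecular_weight,endpoint_type,endpoint_value,endpoint_unit,drc_model,drc_unit,alpha,beta,gamma,delta
PFOA,335-67-1,substance,solid,33.334,414.06,,,,Hill_three,uM,8.0,1.0,0.62,
PFNA,375-95-1,substance,solid,33.333,464.07,,,,Hill_three,uM,15.0,1.0,0.68,
PFDA,335-76-2,substance,solid,33.333,514.08,,,,Hill_three,uM,30.0,1.0,0.75,
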