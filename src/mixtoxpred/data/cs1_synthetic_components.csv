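# product_name: synthetic 23-pesticide mixture (synthetic stand-in parameters)
# output_unit: uM
# endpoint_type: EC50
name,cas,component_type,physical_state,composition_percent,molecular_weight,endpoint_type,endpoint_value,endpoint_unit,drc_model,drc_unit,alpha,beta,gamma,delta
atrazine,1912-24-9,substance,liquid,6.202,215.69,,,,Logit,uM,0.1613,2.707,,
simazine,122-34-9,substance,liquid,5.933,201.66,,,,Weibull,uM,0.91275,1.3008,,
terbuthylazine,5915-41-3,substance,liquid,1.721,229.72,,,,Hill,uM,2.40545,1.3644,,
propazine,139-40-2,substance,liquid,2.867,229.72,,,,Hill_three,uM,12.74789,2.2225,0.967,
diuron,330-54-1,substance,liquid,5.636,233.1,,,,Logit,uM,-2.94839,2.2481,,
isoproturon,34123-59-6,substance,liquid,9.704,206.29,,,,Weibull,uM,-2.1937,1.6837,,
linuron,330-55-2,substance,liquid,4.535,249.1,,,,Hill,uM,0.60431,2.2654,,
metribuzin,21087-64-9,substance,liquid,5.654,214.29,,,,Hill_three,uM,11.70013,2.1991,0.974,
chlorpyrifos,2921-88-2,substance,liquid,3.53,350.59,,,,Logit,uM,1.48034,2.3232,,
diazinon,333-41-5,substance,liquid,4.106,304.35,,,,Weibull,uM,-2.38445,1.9743,,
malathion,121-75-5,substance,liquid,1.691,330.36,,,,Hill,uM,19.38055,1.9113,,
parathion,56-38-2,substance,liquid,3.22,291.27,,,,Hill_three,uM,38.34681,3.1456,0.965,
carbaryl,63-25-2,substance,liquid,2.474,201.22,,,,Logit,uM,0.75839,2.8988,,
carbofuran,1563-66-2,substance,liquid,6.564,221.26,,,,Weibull,uM,-0.74422,1.3534,,
aldicarb,116-06-3,substance,liquid,6.7,190.27,,,,Hill,uM,0.05098,2.7082,,
pirimicarb,23103-98-2,substance,liquid,10.079,238.29,,,,Hill_three,uM,4.80409,2.6726,0.933,
metolachlor,51218-45-2,substance,liquid,1.955,283.8,,,,Logit,uM,-1.61418,1.21,,
alachlor,15972-60-8,substance,liquid,1.57,269.77,,,,Weibull,uM,-3.24529,2.2169,,
pendimethalin,40487-42-1,substance,liquid,2.64,281.31,,,,Hill,uM,44.88496,3.0046,,
trifluralin,1582-09-8,substance,liquid,4.078,335.28,,,,Hill_three,uM,0.05192,1.3765,0.977,
"2,4-D",94-75-7,substance,liquid,1.915,221.04,,,,Logit,uM,-0.5077,1.6248,,
MCPA,94-74-6,substance,liquid,3.443,200.62,,,,Weibull,uM,-1.11063,2.5822,,
mecoprop,93-65-2,substance,liquid,3.783,214.65,,,,Hill,uM,2.60263,1.8877,,
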