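# Resource ledger for the hypertension management programme and usual care,
# 2010 International Dollars. Quantities are annual: hours for labour, units
# for capital goods, m2-months for rented office space, calls/visits/items
# for the rest. Direct annual amounts (software, drug consumption) are
# recorded with quantity 1. Sub-dollar tariffs (telephone calls, per-visit
# overhead, ambulance fee) are kept at four decimals; two-decimal rounding
# of such unit prices would distort the subtotals they generate.
# Categories: labour/capital/land/resource are whole-programme totals;
# overhead/visit/consumption are per patient-year.
strategy,item,category,group,unit_cost,quantity
programme,Physicians,labour,,15.73,3168
programme,Fellows,labour,,10.27,4752
programme,Monitors,labour,,5.29,15744
programme,Education coordinator,labour,,24.22,204
programme,Educational workshops,labour,,20.76,564.03
programme,Secretary,labour,,6.60,528
programme,Nurse,labour,,7.93,13305.60
programme,Epidemiologist,labour,,14.16,120
programme,Coordinator's furnishings,capital,,2901.14,1
programme,Offices' furnishings,capital,,2238.88,1
programme,Sphygmomanometer,capital,,90.50,7
programme,Coordinator's computers,capital,,1703.98,5
programme,Offices' computers,capital,,1703.98,4.20
programme,Administrative office,land,,112.09,90
programme,Medical office,land,,112.09,90
programme,Support office,land,,32.38,378
programme,Workshop space,land,,16.61,564.03
programme,Effective call,resource,telephone,0.1221,7959.96
programme,Ineffective call (non-response),resource,telephone,0.0407,7280.04
programme,Brochures,resource,brochures,1.07,10000
programme,Surveillance software licence,resource,software,4151.60,1
programme,Hardware support,resource,software,5579.75,1
programme,Software maintenance,resource,software,18.52,2376
programme,Software office,resource,software,112.09,36
programme,Software development,resource,software,11588.72,1
programme,Server,resource,software,3397.26,1
programme,Computer,resource,software,374.83,1
programme,Overhead,overhead,,1.9742,8.14
programme,Primary care physician visits,visit,,9.63,7.40
programme,Specialist visits,visit,,9.63,0.74
programme,Emergency ambulance service,visit,,1.4533,12
programme,Drugs,consumption,,198.99,1
programme,Diagnostic/follow-up tests,consumption,,36.19,1
usual,Overhead,overhead,,1.9738,7.64
usual,Primary care physician visits,visit,,9.63,6.90
usual,Specialist visits,visit,,9.63,0.74
usual,Emergency ambulance service,visit,,1.4533,12
usual,Drugs,consumption,,160.48,1
usual,Diagnostic/follow-up tests,consumption,,29.10,1
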