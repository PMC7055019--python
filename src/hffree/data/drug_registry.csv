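name,kind,ingredients,classes
digoxin,ingredient,digoxin,digoxin
lanoxin,brand,digoxin,
digitek,brand,digoxin,
lisinopril,ingredient,lisinopril,ace_inhibitor
prinivil,brand,lisinopril,
zestril,brand,lisinopril,
enalapril,ingredient,enalapril,ace_inhibitor
vasotec,brand,enalapril,
captopril,ingredient,captopril,ace_inhibitor
capoten,brand,captopril,
ramipril,ingredient,ramipril,ace_inhibitor
altace,brand,ramipril,
benazepril,ingredient,benazepril,ace_inhibitor
lotensin,brand,benazepril,
quinapril,ingredient,quinapril,ace_inhibitor
accupril,brand,quinapril,
fosinopril,ingredient,fosinopril,ace_inhibitor
monopril,brand,fosinopril,
trandolapril,ingredient,trandolapril,ace_inhibitor
mavik,brand,trandolapril,
moexipril,ingredient,moexipril,ace_inhibitor
univasc,brand,moexipril,
perindopril,ingredient,perindopril,ace_inhibitor
aceon,brand,perindopril,
losartan,ingredient,losartan,arb
cozaar,brand,losartan,
valsartan,ingredient,valsartan,arb
diovan,brand,valsartan,
irbesartan,ingredient,irbesartan,arb
avapro,brand,irbesartan,
candesartan,ingredient,candesartan,arb
atacand,brand,candesartan,
telmisartan,ingredient,telmisartan,arb
micardis,brand,telmisartan,
olmesartan,ingredient,olmesartan,arb
benicar,brand,olmesartan,
eprosartan,ingredient,eprosartan,arb
teveten,brand,eprosartan,
metoprolol,ingredient,metoprolol,beta_blocker
lopressor,brand,metoprolol,
toprol xl,brand,metoprolol,
atenolol,ingredient,atenolol,beta_blocker
tenormin,brand,atenolol,
propranolol,ingredient,propranolol,beta_blocker
inderal,brand,propranolol,
bisoprolol,ingredient,bisoprolol,beta_blocker
zebeta,brand,bisoprolol,
nadolol,ingredient,nadolol,beta_blocker
corgard,brand,nadolol,
labetalol,ingredient,labetalol,beta_blocker
trandate,brand,labetalol,
normodyne,brand,labetalol,
acebutolol,ingredient,acebutolol,beta_blocker
sectral,brand,acebutolol,
pindolol,ingredient,pindolol,beta_blocker
visken,brand,pindolol,
betaxolol,ingredient,betaxolol,beta_blocker
kerlone,brand,betaxolol,
timolol,ingredient,timolol,beta_blocker
blocadren,brand,timolol,
sotalol,ingredient,sotalol,beta_blocker
betapace,brand,sotalol,
carvedilol,ingredient,carvedilol,beta_blocker|carvedilol
coreg,brand,carvedilol,
spironolactone,ingredient,spironolactone,spironolactone
aldactone,brand,spironolactone,
eplerenone,ingredient,eplerenone,
inspra,brand,eplerenone,
furosemide,ingredient,furosemide,loop_diuretic
lasix,brand,furosemide,
bumetanide,ingredient,bumetanide,loop_diuretic
bumex,brand,bumetanide,
torsemide,ingredient,torsemide,loop_diuretic
demadex,brand,torsemide,
hydralazine,ingredient,hydralazine,hydralazine
apresoline,brand,hydralazine,
isosorbide dinitrate,ingredient,isosorbide dinitrate,nitrate
isordil,brand,isosorbide dinitrate,
dilatrate,brand,isosorbide dinitrate,
isosorbide mononitrate,ingredient,isosorbide mononitrate,nitrate
imdur,brand,isosorbide mononitrate,
ismo,brand,isosorbide mononitrate,
monoket,brand,isosorbide mononitrate,
nitroglycerin,ingredient,nitroglycerin,nitrate
nitrostat,brand,nitroglycerin,
nitro-dur,brand,nitroglycerin,
nitroquick,brand,nitroglycerin,
hydrochlorothiazide,ingredient,hydrochlorothiazide,
hydrodiuril,brand,hydrochlorothiazide,
zestoretic,brand,lisinopril|hydrochlorothiazide,
prinzide,brand,lisinopril|hydrochlorothiazide,
hyzaar,brand,losartan|hydrochlorothiazide,
diovan hct,brand,valsartan|hydrochlorothiazide,
avalide,brand,irbesartan|hydrochlorothiazide,
aldactazide,brand,spironolactone|hydrochlorothiazide,
bidil,brand,hydralazine|isosorbide dinitrate,
lopressor hct,brand,metoprolol|hydrochlorothiazide,
tenoretic,brand,atenolol|chlorthalidone,
chlorthalidone,ingredient,chlorthalidone,
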